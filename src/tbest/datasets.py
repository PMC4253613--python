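"""Synthetic datasets for exercising and validating the branch-significance test.

Three generators mirror the designs used to validate the method:

- a one-dimensional 3-component normal mixture (280 points from
  N(0.5, 0.4^2), N(11, 1^2) and N(5, 2^2)) whose two outer components form
  visibly distinct, approximately equally tight branches under single
  linkage on absolute differences;
- a simulated gene-expression design ("Simulated6"): 60 observations by
  600 variables, six subtypes of sizes 8, 12, 10, 15, 5 and 10, 300
  background genes shared by all subtypes and six disjoint 50-gene blocks
  each up-regulated in exactly one subtype; one exceptional observation
  (column 8 of the transposed original layout) has both the subtype-1 and
  subtype-2 blocks up-regulated;
- plain noise and Bernoulli binary matrices for null calibration and for
  fixed-margin randomization tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MixtureSpec1D",
    "Simulated6Spec",
    "gen_mixture_1d",
    "gen_simulated6",
    "gen_noise_matrix",
    "gen_binary_matrix",
]


@dataclass
class MixtureSpec1D:
    """A univariate normal mixture: (mean, sd, weight) components.

    Defaults reproduce the illustrative mixture: components at 0.5 (sd 0.4),
    11 (sd 1) and 5 (sd 2); the component weights are not part of the
    published design and default to (0.25, 0.25, 0.50) so the two outer
    components form clearly distinct branches against a broad background.
    """

    components: tuple[tuple[float, float, float], ...] = (
        (0.5, 0.4, 0.25),
        (11.0, 1.0, 0.25),
        (5.0, 2.0, 0.50),
    )
    n: int = 280

    def __post_init__(self) -> None:
        w = np.array([c[2] for c in self.components])
        if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("component weights must be positive and sum to 1")
        if any(c[1] <= 0 for c in self.components):
            raise ValueError("component standard deviations must be positive")
        if self.n < 3:
            raise ValueError("need at least 3 points")


def gen_mixture_1d(
    spec: MixtureSpec1D | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw an n x 1 data matrix from the mixture; returns (matrix, component labels)."""
    spec = spec or MixtureSpec1D()
    rng = np.random.default_rng(seed)
    means, sds, weights = (np.array(x) for x in zip(*spec.components))
    comp = rng.choice(len(means), size=spec.n, p=weights)
    x = rng.normal(means[comp], sds[comp])
    df = pd.DataFrame({"x": x}, index=[f"obs{i}" for i in range(spec.n)])
    return df, comp


@dataclass
class Simulated6Spec:
    """Design of the six-subtype simulated expression matrix."""

    class_sizes: tuple[int, ...] = (8, 12, 10, 15, 5, 10)
    n_background: int = 300
    block_size: int = 50
    effect_shift: float = 2.5  # up-regulation, in background-SD units
    #: 0-based observation index given a second up-regulated block (a deliberate
    #: violation of the 6-class truth; 7 reproduces the published design's
    #: exceptional column 8). Off by default: the clean design is the baseline.
    exceptional_column: int | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("class sizes must be positive")
        if self.n_background < 0 or self.block_size < 1:
            raise ValueError("invalid gene counts")
        if self.exceptional_column is not None and not (
            0 <= self.exceptional_column < self.n_obs
        ):
            raise ValueError("exceptional_column outside the observation range")

    @property
    def n_obs(self) -> int:
        return sum(self.class_sizes)

    @property
    def n_vars(self) -> int:
        return self.n_background + len(self.class_sizes) * self.block_size


def gen_simulated6(
    spec: Simulated6Spec | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate the six-subtype matrix; returns (matrix, truth labels).

    Background genes are i.i.d. standard normal for every observation; block
    ``j`` is shifted upward by ``effect_shift`` for the observations of
    class ``j`` only.  The exceptional observation (a member of the first
    subtype) additionally has the second subtype's block up-shifted.
    """
    spec = spec or Simulated6Spec()
    rng = np.random.default_rng(seed)
    n, p = spec.n_obs, spec.n_vars
    truth = np.repeat(np.arange(len(spec.class_sizes)), spec.class_sizes)
    values = rng.normal(size=(n, p))
    for j in range(len(spec.class_sizes)):
        cols = slice(spec.n_background + j * spec.block_size, spec.n_background + (j + 1) * spec.block_size)
        values[truth == j, cols] += spec.effect_shift
    if spec.exceptional_column is not None:
        extra = 1 if truth[spec.exceptional_column] != 1 else 0
        cols = slice(
            spec.n_background + extra * spec.block_size,
            spec.n_background + (extra + 1) * spec.block_size,
        )
        values[spec.exceptional_column, cols] += spec.effect_shift
    obs = [f"obs{i}" for i in range(n)]
    var = [f"bg{i}" for i in range(spec.n_background)] + [
        f"block{j}_g{i}"
        for j in range(len(spec.class_sizes))
        for i in range(spec.block_size)
    ]
    return pd.DataFrame(values, index=obs, columns=var), truth


def gen_noise_matrix(n_obs: int, n_vars: int, seed: int | None = None) -> pd.DataFrame:
    """An n_obs x n_vars matrix of i.i.d. standard-normal entries."""
    if n_obs < 3:
        raise ValueError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_obs, n_vars)),
        index=[f"obs{i}" for i in range(n_obs)],
        columns=[f"v{j}" for j in range(n_vars)],
    )


def gen_binary_matrix(
    n_obs: int, n_vars: int, density: float = 0.2, seed: int | None = None
) -> pd.DataFrame:
    """An i.i.d. Bernoulli(density) 0/1 matrix (e.g. a mutation-status matrix)."""
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        (rng.random(size=(n_obs, n_vars)) < density).astype(int),
        index=[f"obs{i}" for i in range(n_obs)],
        columns=[f"v{j}" for j in range(n_vars)],
    )
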