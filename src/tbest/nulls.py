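"""Leaf-count-matched null samples of tightness.

The null distribution of tightness depends strongly on the number of leaves
under a node (small branches of randomized data are tighter on average), so
each observed node must be compared against null values from nodes of
matching size.  For every randomization of the data a tree is grown and, for
each observed leaf count ``k``:

- if the null tree has nodes with exactly ``k`` leaves, the highest tightness
  among them joins the sample;
- otherwise the highest tightness among all nodes at the nearest leaf count
  below ``k`` and all nodes at the nearest count above ``k`` joins the sample
  (one-sided when only one neighbour exists).

Taking maxima over the candidate nodes makes the sampled null
stochastically larger than any single matched node's tightness, i.e. the
resulting test errs on the conservative side.  Leaves (k = 1) always have
tightness exactly 1 and are never tested, so k >= 2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .randomization import randomize
from .tree import Dendrogram, compute_dissimilarity

__all__ = [
    "NullSamples",
    "max_tightness_by_leafcount",
    "sample_null_for_count",
    "build_null_samples",
]


def _node_stats(Z: np.ndarray, statistic: str) -> tuple[np.ndarray, np.ndarray]:
    """Leaf counts and tightness of the eligible internal nodes of a linkage matrix.

    Vectorized hot path used once per randomization; excludes the root for
    the parent statistic (it has no parent), includes it for the children
    statistic.
    """
    L = Z.shape[0] + 1
    heights = Z[:, 2]
    counts = Z[:, 3].astype(int)
    if statistic == "parent":
        hp = np.empty(L - 1)
        hp.fill(np.nan)
        children = Z[:, :2].astype(int)
        internal = children >= L
        for i in range(L - 1):
            if internal[i, 0]:
                hp[children[i, 0] - L] = heights[i]
            if internal[i, 1]:
                hp[children[i, 1] - L] = heights[i]
        keep = np.arange(L - 1) != (L - 2)  # drop the root
        h, hp, counts = heights[keep], hp[keep], counts[keep]
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(hp > 0, (hp - h) / hp, 0.0)
    elif statistic == "children":
        h_all = np.concatenate([np.zeros(L), heights])
        children = Z[:, :2].astype(int)
        hmax = np.maximum(h_all[children[:, 0]], h_all[children[:, 1]])
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(heights > 0, (heights - hmax) / heights, 0.0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return counts, S


def max_tightness_by_leafcount(counts: np.ndarray, S: np.ndarray) -> dict[int, float]:
    """Maximum tightness per distinct leaf count.

    ``counts`` and ``S`` are parallel arrays over eligible internal nodes
    (e.g. the columns of a tightness table).
    """
    counts = np.asarray(counts, dtype=int)
    S = np.asarray(S, dtype=float)
    out: dict[int, float] = {}
    for k, s in zip(counts, S):
        k = int(k)
        if k not in out or s > out[k]:
            out[k] = float(s)
    return out


def sample_null_for_count(nullmap: Mapping[int, float], k: int) -> float:
    """One null value for leaf count ``k`` from a null tree's per-count maxima.

    Exact match if available; otherwise the maximum over the nearest counts
    below and above ``k`` (whichever exist).
    """
    if not nullmap:
        raise ValueError("empty null tree summary: no eligible internal nodes")
    if k in nullmap:
        return nullmap[k]
    below = [c for c in nullmap if c < k]
    above = [c for c in nullmap if c > k]
    candidates = []
    if below:
        candidates.append(nullmap[max(below)])
    if above:
        candidates.append(nullmap[min(above)])
    return max(candidates)


def _sample_for_counts_sorted(
    null_keys: np.ndarray, null_max: np.ndarray, ks: np.ndarray
) -> np.ndarray:
    """Vectorized form of :func:`sample_null_for_count` over sorted null keys."""
    idx = np.searchsorted(null_keys, ks)
    out = np.empty(ks.shape[0])
    for j, (k, i) in enumerate(zip(ks, idx)):
        if i < null_keys.size and null_keys[i] == k:
            out[j] = null_max[i]
        else:
            lo = null_max[i - 1] if i > 0 else -np.inf
            hi = null_max[i] if i < null_keys.size else -np.inf
            out[j] = max(lo, hi)
    return out


@dataclass
class NullSamples:
    """Per-leaf-count vectors of max-tightness values from randomized trees."""

    counts: np.ndarray  # sorted distinct observed leaf counts, shape (K,)
    samples: np.ndarray  # shape (K, n_perm), rows parallel to `counts`

    @property
    def n_perm(self) -> int:
        return self.samples.shape[1]

    def for_count(self, k: int) -> np.ndarray:
        idx = np.flatnonzero(self.counts == k)
        if idx.size == 0:
            raise KeyError(f"no null sample was built for leaf count {k}")
        return self.samples[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        """Long-form audit table (perm_index, k, S)."""
        K, M = self.samples.shape
        return pd.DataFrame(
            {
                "perm_index": np.tile(np.arange(M), K),
                "k": np.repeat(self.counts, M),
                "S": self.samples.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NullSamples":
        pivot = frame.pivot(index="k", columns="perm_index", values="S").sort_index()
        return cls(counts=pivot.index.to_numpy(int), samples=pivot.to_numpy(float))


def build_null_samples(
    values: np.ndarray,
    observed_counts: Sequence[int],
    metric: str = "euclidean",
    linkage: str = "complete",
    scheme: str = "columns",
    statistic: str = "parent",
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    group_ids: Sequence | None = None,
    n_swaps: int | None = None,
) -> NullSamples:
    """Sample the leaf-count-matched null by repeated data randomization.

    Each of the ``n_perm`` randomizations serves every observed leaf count at
    once: randomize the matrix, grow the tree, take per-count maxima of
    tightness, then apply the matching rule for each ``k`` in
    ``observed_counts``.  Randomness is index-addressed: permutation ``i``
    uses the ``i``-th child stream of ``seed``, so results do not depend on
    execution order.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(values, dtype=float)
    ks = np.asarray(sorted(set(int(k) for k in observed_counts)), dtype=int)
    if ks.size and ks.min() < 2:
        raise ValueError("leaf counts below 2 are never tested (leaves are identically tight)")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    streams = ss.spawn(n_perm)
    samples = np.empty((ks.size, n_perm))
    for i in range(n_perm):
        rng = np.random.default_rng(streams[i])
        try:
            perm = randomize(values, scheme, rng, group_ids=group_ids, n_swaps=n_swaps)
            d = compute_dissimilarity(perm, metric)
            Z = hierarchy.linkage(d, method=linkage)
        except Exception as exc:  # attach the permutation index for debugging
            raise RuntimeError(f"null randomization {i} failed: {exc}") from exc
        counts, S = _node_stats(Z, statistic)
        order = np.argsort(counts, kind="stable")
        counts, S = counts[order], S[order]
        # per-count maxima on the sorted arrays
        keys, start = np.unique(counts, return_index=True)
        maxima = np.maximum.reduceat(S, start)
        samples[:, i] = _sample_for_counts_sorted(keys, maxima, ks)
    return NullSamples(counts=ks, samples=samples)
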