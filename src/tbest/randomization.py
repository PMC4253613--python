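"""Data randomization schemes for sampling the null distribution of tightness.

The null distribution is always obtained by randomizing the *data matrix*
and re-growing the tree — never by shuffling the dissimilarities.  Which
randomization is appropriate depends on the data:

- ``columns``: permute the values of every variable (column) independently;
  destroys all structure among observations while preserving each marginal.
- ``grouped``: variables are divided into groups (e.g. genomic cores by
  chromosome) and one row permutation is applied jointly to all columns of a
  group, preserving within-group dependence between variables.
- ``margins``: for strictly 0/1 matrices, a checkerboard-swap Markov chain
  that preserves every row sum and column sum.
- ``pool``: resample every entry with replacement from the pooled empirical
  distribution of the whole matrix; the scheme used for one-dimensional
  data, where per-column permutation would leave the tree unchanged.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SCHEMES",
    "permute_columns_independent",
    "permute_grouped",
    "randomize_fixed_margins",
    "resample_pooled",
    "randomize",
]

SCHEMES = ("columns", "grouped", "margins", "pool")


def permute_columns_independent(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each column's values independently of the others."""
    values = np.asarray(values, dtype=float)
    return rng.permuted(values, axis=0)


def permute_grouped(
    values: np.ndarray,
    group_ids: Sequence,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply one independent row permutation per group of columns.

    ``group_ids`` assigns a group to each column (length = n_vars).  Within a
    group the rows of the sub-matrix travel as intact tuples, so dependence
    between the group's variables is preserved exactly.
    """
    values = np.asarray(values, dtype=float)
    group_ids = np.asarray(group_ids)
    if group_ids.shape[0] != values.shape[1]:
        raise ValueError(
            f"group assignment covers {group_ids.shape[0]} variables "
            f"but the matrix has {values.shape[1]}"
        )
    out = np.empty_like(values)
    for g in np.unique(group_ids):
        cols = np.flatnonzero(group_ids == g)
        perm = rng.permutation(values.shape[0])
        out[:, cols] = values[np.ix_(perm, cols)]
    return out


def randomize_fixed_margins(
    values: np.ndarray,
    rng: np.random.Generator,
    n_swaps: int | None = None,
    max_tries_factor: int = 100,
) -> np.ndarray:
    """Randomize a binary matrix preserving all row and column sums.

    Runs a checkerboard Markov chain: repeatedly pick a 2x2 sub-matrix and,
    when it equals ``[[1,0],[0,1]]`` or ``[[0,1],[1,0]]``, swap it.  Stops
    after ``n_swaps`` accepted swaps (default 10x the number of ones, a
    common burn-in heuristic) or after ``max_tries_factor * n_swaps``
    attempts, whichever comes first (matrices with a unique margin-preserving
    configuration, such as all-ones, accept no swaps at all).
    """
    values = np.asarray(values)
    if not np.isin(values, (0, 1)).all():
        raise ValueError("fixed-margin randomization requires a strictly 0/1 matrix")
    out = values.astype(float).copy()
    n_ones = int(out.sum())
    if n_swaps is None:
        n_swaps = 10 * n_ones
    n_rows, n_cols = out.shape
    if n_rows < 2 or n_cols < 2 or n_swaps == 0:
        return out
    accepted = 0
    for _ in range(max_tries_factor * max(n_swaps, 1)):
        if accepted >= n_swaps:
            break
        r1, r2 = rng.choice(n_rows, size=2, replace=False)
        c1, c2 = rng.choice(n_cols, size=2, replace=False)
        a, b, c, d = out[r1, c1], out[r1, c2], out[r2, c1], out[r2, c2]
        if a == d and b == c and a != b:
            out[r1, c1], out[r2, c2] = b, b
            out[r1, c2], out[r2, c1] = a, a
            accepted += 1
    return out


def resample_pooled(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample every entry i.i.d. from the pooled empirical distribution."""
    values = np.asarray(values, dtype=float)
    flat = values.ravel()
    return rng.choice(flat, size=values.shape, replace=True)


def randomize(
    values: np.ndarray,
    scheme: str,
    rng: np.random.Generator,
    group_ids: Sequence | None = None,
    n_swaps: int | None = None,
) -> np.ndarray:
    """Dispatch to the named randomization scheme."""
    if scheme == "columns":
        return permute_columns_independent(values, rng)
    if scheme == "grouped":
        if group_ids is None:
            raise ValueError("scheme='grouped' requires a group assignment for every variable")
        return permute_grouped(values, group_ids, rng)
    if scheme == "margins":
        return randomize_fixed_margins(values, rng, n_swaps=n_swaps)
    if scheme == "pool":
        return resample_pooled(values, rng)
    raise ValueError(f"unknown randomization scheme {scheme!r}; choose from {SCHEMES}")
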