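"""Permutation p-values for tightness, EVT tail sharpening, multiplicity correction.

Empirical p-values use the add-one convention p_e = (1 + #{null >= S}) / (1 + M)
(never zero, ties counted as exceedances).  Because every internal node except
the root is tested — N - 2 tests on a tree with N leaves — a family-wise
correction is applied; with M permutations the smallest reachable empirical
p-value is 1/(M+1), which for large trees cannot clear the corrected
threshold at any reasonable M.  The tail of the null is therefore
approximated with extreme-value theory: exceedances over a high quantile of
the null sample are fitted by a generalized Pareto distribution (GPD) by
maximum likelihood, giving access to p-values far below 1/M at fixed
computational cost.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .nulls import NullSamples

__all__ = ["empirical_p", "evt_p", "correct_p", "significance_table"]

_EPS = np.finfo(float).eps
#: minimum number of exceedances for a GPD fit to be attempted
_MIN_EXCEEDANCES = 10
#: Kolmogorov-Smirnov p-value below which the tail fit is rejected and the
#: threshold raised (tail fraction halved)
_GOF_ALPHA = 0.05


def empirical_p(S_obs: float, null: np.ndarray) -> float:
    """Add-one empirical p-value of an observed tightness against a null sample."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null sample")
    return float((1 + np.count_nonzero(null >= S_obs)) / (1 + null.size))


def _fit_tail(exceedances: np.ndarray) -> tuple[float, float] | None:
    """ML fit of a GPD (location 0) to threshold exceedances; None if degenerate."""
    if exceedances.size < _MIN_EXCEEDANCES or np.ptp(exceedances) == 0:
        return None
    shape, _, scale = stats.genpareto.fit(exceedances, floc=0.0)
    if not np.isfinite(shape) or not np.isfinite(scale) or scale <= 0:
        return None
    ks = stats.kstest(exceedances, stats.genpareto(shape, loc=0.0, scale=scale).cdf)
    if ks.pvalue < _GOF_ALPHA:
        return None
    return float(shape), float(scale)


def evt_p(S_obs: float, null: np.ndarray, tail_fraction: float = 0.1) -> float:
    """Tail-refined p-value via a generalized Pareto fit to the null's upper tail.

    Below the tail threshold (the ``1 - tail_fraction`` quantile of the null
    sample) the empirical p-value is returned unchanged.  Above it, the GPD
    survival function is scaled by the exceedance rate:

        p = (n_exc / M) * (1 - F_GPD(S_obs - threshold))

    floored at machine epsilon.  If the fit is degenerate or fails a
    Kolmogorov-Smirnov goodness-of-fit check, the threshold is raised
    (tail fraction halved, twice at most) and finally the empirical p-value
    is returned with a warning.
    """
    null = np.asarray(null, dtype=float)
    if null.size < 100:
        raise ValueError("EVT tail fitting needs at least 100 null values for stability")
    if not 0 < tail_fraction < 1:
        raise ValueError("tail_fraction must be in (0, 1)")
    M = null.size
    for frac in (tail_fraction, tail_fraction / 2, tail_fraction / 4):
        threshold = np.quantile(null, 1 - frac)
        if S_obs <= threshold:
            return empirical_p(S_obs, null)
        exceedances = null[null > threshold] - threshold
        fit = _fit_tail(exceedances)
        if fit is not None:
            shape, scale = fit
            sf = stats.genpareto.sf(S_obs - threshold, shape, loc=0.0, scale=scale)
            return float(max((exceedances.size / M) * sf, _EPS))
    warnings.warn(
        "degenerate null tail: generalized Pareto fit failed at every threshold; "
        "falling back to the empirical p-value",
        RuntimeWarning,
        stacklevel=2,
    )
    return empirical_p(S_obs, null)


def correct_p(p_e: float, n_leaves: int, method: str = "sidak") -> float:
    """Family-wise correction over the N - 2 tested nodes of an N-leaf tree.

    Šidák by default: p = 1 - (1 - p_e)^(N-2); Bonferroni available as
    ``method="bonferroni"``: p = min(1, (N-2) * p_e).
    """
    if not 0 <= p_e <= 1:
        raise ValueError(f"p-value {p_e} outside [0, 1]")
    if n_leaves < 3:
        raise ValueError("trees with fewer than 3 leaves have no testable nodes")
    n_tests = n_leaves - 2
    if method == "sidak":
        # expm1/log1p form stays accurate for tiny p
        return float(-np.expm1(n_tests * np.log1p(-p_e))) if p_e < 1 else 1.0
    if method == "bonferroni":
        return float(min(1.0, n_tests * p_e))
    raise ValueError(f"unknown correction {method!r}; choose 'sidak' or 'bonferroni'")


def significance_table(
    tightness: pd.DataFrame,
    null_samples: NullSamples,
    n_leaves: int,
    use_evt: bool = True,
    tail_fraction: float = 0.1,
    correction: str = "sidak",
) -> pd.DataFrame:
    """Per-node significance of observed tightness.

    One row per tested node with columns node_id, leaf_count, S, p_empirical,
    p_evt (NaN when ``use_evt`` is off), p_corrected.  ``p_corrected`` is the
    family-wise corrected version of the EVT p-value when ``use_evt`` is on,
    of the empirical one otherwise.
    """
    rows = []
    for node_id, k, S_obs in zip(
        tightness["node_id"].to_numpy(int),
        tightness["leaf_count"].to_numpy(int),
        tightness["S"].to_numpy(float),
    ):
        null = null_samples.for_count(k)
        p_e = empirical_p(S_obs, null)
        p_t = evt_p(S_obs, null, tail_fraction) if use_evt else np.nan
        base = p_t if use_evt else p_e
        rows.append(
            {
                "node_id": node_id,
                "leaf_count": k,
                "S": S_obs,
                "p_empirical": p_e,
                "p_evt": p_t,
                "p_corrected": correct_p(base, n_leaves, method=correction),
            }
        )
    return pd.DataFrame(
        rows, columns=["node_id", "leaf_count", "S", "p_empirical", "p_evt", "p_corrected"]
    )
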