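"""Scikit-learn-style estimator running the full branch-significance pipeline."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .nulls import build_null_samples
from .partition import most_detailed_partition
from .randomization import SCHEMES
from .significance import significance_table
from .tightness import STATISTICS, tightness_all
from .tree import LINKAGES, METRICS, grow_tree


class TBEST(ClusterMixin, BaseEstimator):
    """Tree Branches Evaluated Statistically for Tightness.

    Grows a hierarchical tree of the observations, scores every internal
    node's distinctness by its tightness (the relative height gap to its
    parent), samples a leaf-count-matched null distribution by randomizing
    the data and re-growing trees, converts observed tightness to
    family-wise-corrected p-values (with an optional generalized-Pareto tail
    refinement for p-values below the permutation resolution), and extracts
    the most detailed partition of the leaves into significantly distinct
    branches.

    Parameters
    ----------
    metric : {'euclidean', 'manhattan', 'pearson', 'spearman', 'kendall'}
        Dissimilarity between observations; correlation metrics mean
        ``1 - r`` between row vectors.
    linkage : {'single', 'complete', 'average', 'ward'}
        Agglomeration rule (all four are inversion-free).
    statistic : {'parent', 'children'}
        Tightness variant: relative gap to the parent (default; the root is
        untested) or relative gap to the taller child.
    scheme : {'columns', 'grouped', 'margins', 'pool'}
        Data randomization for the null: independent per-column permutation,
        jointly-permuted column groups, fixed-margin checkerboard swaps for
        binary data, or pooled resampling (for one-dimensional data).
    groups : sequence, optional
        Per-variable group ids, required for ``scheme='grouped'``.
    n_perm : int
        Number of data randomizations for the null sample.
    alpha : float
        Family-wise significance threshold for the partition (strict
        inequality).
    use_evt : bool
        Refine tail p-values with a generalized Pareto fit to the null's
        upper tail; needed whenever the corrected threshold lies below the
        1/(n_perm+1) resolution of empirical p-values.
    tail_fraction : float
        Fraction of the null sample treated as tail for the Pareto fit.
    correction : {'sidak', 'bonferroni'}
        Family-wise multiplicity correction over the N - 2 tested nodes.
    n_swaps : int, optional
        Accepted-swap budget for ``scheme='margins'``.
    random_state : int, optional
        Seed for the randomization streams.

    Attributes
    ----------
    tree_ : Dendrogram
        The observed hierarchical tree.
    tightness_ : pandas.DataFrame
        Per-node tightness (node_id, leaf_count, S).
    null_samples_ : NullSamples
        Leaf-count-matched null tightness samples.
    significance_ : pandas.DataFrame
        Per-node p-values (empirical, EVT, corrected).
    partition_ : Partition
        The most detailed significant partition at ``alpha``.
    labels_ : ndarray of shape (n_observations,)
        Part id per observation (all 1 when nothing is significant).
    n_parts_ : int
    is_significant_ : bool

    Examples
    --------
    >>> from tbest import TBEST, gen_simulated6
    >>> X, truth = gen_simulated6(seed=0)
    >>> model = TBEST(n_perm=200, random_state=0).fit(X)
    >>> model.n_parts_
    6
    """

    def __init__(
        self,
        metric: str = "euclidean",
        linkage: str = "complete",
        statistic: str = "parent",
        scheme: str = "columns",
        groups: Sequence | None = None,
        n_perm: int = 1000,
        alpha: float = 0.05,
        use_evt: bool = True,
        tail_fraction: float = 0.1,
        correction: str = "sidak",
        n_swaps: int | None = None,
        random_state: int | None = None,
    ):
        self.metric = metric
        self.linkage = linkage
        self.statistic = statistic
        self.scheme = scheme
        self.groups = groups
        self.n_perm = n_perm
        self.alpha = alpha
        self.use_evt = use_evt
        self.tail_fraction = tail_fraction
        self.correction = correction
        self.n_swaps = n_swaps
        self.random_state = random_state

    def _validate_params_(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")
        if self.statistic not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def fit(self, X, y=None):
        """Run the full pipeline on an observations x variables matrix."""
        self._validate_params_()
        obs_labels = list(X.index.astype(str)) if isinstance(X, pd.DataFrame) else None
        X = validate_data(self, X, ensure_min_samples=3, dtype=float)
        self.tree_ = grow_tree(X, metric=self.metric, linkage=self.linkage, labels=obs_labels)
        self.tightness_ = tightness_all(self.tree_, statistic=self.statistic)
        self.null_samples_ = build_null_samples(
            X,
            observed_counts=self.tightness_["leaf_count"],
            metric=self.metric,
            linkage=self.linkage,
            scheme=self.scheme,
            statistic=self.statistic,
            n_perm=self.n_perm,
            seed=self.random_state,
            group_ids=self.groups,
            n_swaps=self.n_swaps,
        )
        self.significance_ = significance_table(
            self.tightness_,
            self.null_samples_,
            n_leaves=self.tree_.n_leaves,
            use_evt=self.use_evt,
            tail_fraction=self.tail_fraction,
            correction=self.correction,
        )
        self.partition_ = most_detailed_partition(self.tree_, self.significance_, self.alpha)
        self.labels_ = self.partition_.labels(self.tree_.n_leaves)
        self.n_parts_ = self.partition_.n_parts
        self.is_significant_ = self.partition_.is_significant
        return self

    def partition_at(self, alpha: float):
        """Most detailed significant partition at another threshold, without refitting."""
        check_is_fitted(self)
        return most_detailed_partition(self.tree_, self.significance_, alpha)


def run_tbest(
    X,
    metric: str = "euclidean",
    linkage: str = "complete",
    **kwargs,
) -> TBEST:
    """Functional wrapper: fit a :class:`TBEST` model and return it."""
    return TBEST(metric=metric, linkage=linkage, **kwargs).fit(X)
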