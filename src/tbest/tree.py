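"""Hierarchical trees: dissimilarities, agglomeration, and the dendrogram container.

A dendrogram here is the standard binary merge tree of agglomerative
clustering: for ``L`` observations there are ``L`` leaves (node ids
``0..L-1``, height 0) and ``L-1`` internal nodes (ids ``L..2L-2``, in merge
order, the root being ``2L-2``), each internal node carrying the
dissimilarity at which its two children were merged and the number of leaves
under it.  Only inversion-free linkage rules (single, complete, average,
Ward) are supported, so every parent is at least as high as its children —
the property the tightness statistic relies on.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, kendalltau

__all__ = [
    "METRICS",
    "LINKAGES",
    "compute_dissimilarity",
    "grow_tree",
    "Dendrogram",
    "parent_map",
    "subtree_leaves",
]

METRICS = ("euclidean", "manhattan", "pearson", "spearman", "kendall")
LINKAGES = ("single", "complete", "average", "ward")

#: numerical slack when checking monotonicity of merge heights
_INVERSION_TOL = 1e-10


def _check_matrix(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"expected a 2-D observations x variables matrix, got ndim={values.ndim}")
    if not np.all(np.isfinite(values)):
        raise ValueError("data matrix contains missing or non-finite values; impute or drop them first")
    return values


def compute_dissimilarity(values: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Pairwise dissimilarities between observations (rows).

    Correlation metrics return ``1 - r`` where ``r`` is the Pearson, Spearman
    or Kendall correlation between row vectors; they require at least two
    variables and reject constant rows (correlation undefined).

    Returns a condensed distance vector (as :func:`scipy.spatial.distance.pdist`).
    """
    values = _check_matrix(values)
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "euclidean":
        return pdist(values, metric="euclidean")
    if metric == "manhattan":
        return pdist(values, metric="cityblock")

    # correlation-based: 1 - r between rows
    if values.shape[1] < 2:
        raise ValueError(f"{metric} dissimilarity requires at least 2 variables")
    sd = values.std(axis=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(
            f"rows {const.tolist()} are constant; {metric} correlation is undefined for them"
        )
    if metric == "pearson":
        d = 1.0 - np.corrcoef(values)
    elif metric == "spearman":
        ranks = rankdata(values, axis=1)
        d = 1.0 - np.corrcoef(ranks)
    else:  # kendall
        n = values.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                tau = kendalltau(values[i], values[j]).statistic
                d[i, j] = d[j, i] = 1.0 - tau
    np.fill_diagonal(d, 0.0)
    # clip tiny negative round-off on the 1 - r scale
    d = np.maximum(d, 0.0)
    return squareform(d, checks=False)


def grow_tree(
    values: np.ndarray,
    metric: str = "euclidean",
    linkage: str = "complete",
    labels: Sequence[str] | None = None,
) -> "Dendrogram":
    """Grow an inversion-free hierarchical tree from a data matrix.

    ``linkage`` must be one of single/complete/average/ward.  Ward on
    non-Euclidean dissimilarities uses the Lance-Williams update on the
    provided dissimilarities (the standard agglomerative convention).
    """
    values = _check_matrix(values)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 observations to cluster")
    if linkage not in LINKAGES:
        raise ValueError(f"unsupported linkage {linkage!r}; choose from {LINKAGES}")
    d = compute_dissimilarity(values, metric)
    Z = hierarchy.linkage(d, method=linkage)
    return Dendrogram(Z, labels=labels)


def grow_tree_from_condensed(
    d: np.ndarray, linkage: str = "complete", labels: Sequence[str] | None = None
) -> "Dendrogram":
    """Grow a tree directly from a condensed dissimilarity vector."""
    if linkage not in LINKAGES:
        raise ValueError(f"unsupported linkage {linkage!r}; choose from {LINKAGES}")
    Z = hierarchy.linkage(np.asarray(d, dtype=float), method=linkage)
    return Dendrogram(Z, labels=labels)


class Dendrogram:
    """Binary merge tree with per-node heights and leaf counts.

    Wraps a scipy linkage matrix ``Z`` of shape ``(L-1, 4)``.  Node ids
    follow the scipy convention: leaves ``0..L-1``, internal nodes
    ``L..2L-2`` in merge order; ``root == 2L-2``.
    """

    def __init__(self, Z: np.ndarray, labels: Sequence[str] | None = None):
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 2 or Z.shape[1] != 4:
            raise ValueError("expected an (L-1) x 4 linkage matrix")
        self.Z = Z
        self.n_leaves = Z.shape[0] + 1
        if labels is None:
            labels = [str(i) for i in range(self.n_leaves)]
        labels = [str(l) for l in labels]
        if len(labels) != self.n_leaves:
            raise ValueError("label count does not match leaf count")
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        self.labels = labels
        self._validate()

    # -- structure -----------------------------------------------------
    def _validate(self) -> None:
        L = self.n_leaves
        heights = self.Z[:, 2]
        counts = self.Z[:, 3].astype(int)
        if np.any(heights < -_INVERSION_TOL):
            raise ValueError("negative merge heights")
        for i in range(L - 1):
            for c in (int(self.Z[i, 0]), int(self.Z[i, 1])):
                hc = 0.0 if c < L else heights[c - L]
                if heights[i] < hc - _INVERSION_TOL:
                    raise ValueError(
                        f"inversion at internal node {L + i}: height {heights[i]} < child height {hc}"
                    )
        for i in range(L - 1):
            c1, c2 = int(self.Z[i, 0]), int(self.Z[i, 1])
            n1 = 1 if c1 < L else counts[c1 - L]
            n2 = 1 if c2 < L else counts[c2 - L]
            if counts[i] != n1 + n2:
                raise ValueError(f"leaf counts inconsistent at internal node {L + i}")

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.arange(self.n_leaves, self.n_nodes)

    def is_leaf(self, node: int) -> bool:
        self._check_node(node)
        return node < self.n_leaves

    def _check_node(self, node: int) -> None:
        if not 0 <= node < self.n_nodes:
            raise KeyError(f"node {node} not in tree with {self.n_nodes} nodes")

    def height(self, node: int) -> float:
        """Merge height of ``node``; 0 for leaves."""
        self._check_node(node)
        return 0.0 if node < self.n_leaves else float(self.Z[node - self.n_leaves, 2])

    def leaf_count(self, node: int) -> int:
        self._check_node(node)
        return 1 if node < self.n_leaves else int(self.Z[node - self.n_leaves, 3])

    def children(self, node: int) -> tuple[int, int]:
        self._check_node(node)
        if node < self.n_leaves:
            raise ValueError(f"node {node} is a leaf and has no children")
        row = self.Z[node - self.n_leaves]
        return int(row[0]), int(row[1])

    def parent_map(self) -> dict[int, int]:
        """Map every non-root node to its parent; the root is absent."""
        pm: dict[int, int] = {}
        L = self.n_leaves
        for i in range(L - 1):
            pm[int(self.Z[i, 0])] = L + i
            pm[int(self.Z[i, 1])] = L + i
        return pm

    def parent_heights(self) -> np.ndarray:
        """Height of the parent of each node, indexed by node id (root -> nan)."""
        hp = np.full(self.n_nodes, np.nan)
        L = self.n_leaves
        for i in range(L - 1):
            hp[int(self.Z[i, 0])] = self.Z[i, 2]
            hp[int(self.Z[i, 1])] = self.Z[i, 2]
        return hp

    def subtree_leaves(self, node: int) -> np.ndarray:
        """Sorted ids of the leaves under ``node`` (a leaf yields itself)."""
        self._check_node(node)
        L = self.n_leaves
        out: list[int] = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n < L:
                out.append(n)
            else:
                row = self.Z[n - L]
                stack.append(int(row[0]))
                stack.append(int(row[1]))
        return np.array(sorted(out), dtype=int)

    # -- export --------------------------------------------------------
    def merge_table(self) -> pd.DataFrame:
        """Flat merge table: one row per internal node."""
        L = self.n_leaves
        return pd.DataFrame(
            {
                "node_id": np.arange(L, 2 * L - 1),
                "child1": self.Z[:, 0].astype(int),
                "child2": self.Z[:, 1].astype(int),
                "height": self.Z[:, 2],
                "leaf_count": self.Z[:, 3].astype(int),
            }
        )

    @classmethod
    def from_merge_table(cls, table: pd.DataFrame, labels: Sequence[str] | None = None) -> "Dendrogram":
        t = table.sort_values("node_id")
        Z = np.column_stack(
            [
                t["child1"].to_numpy(float),
                t["child2"].to_numpy(float),
                t["height"].to_numpy(float),
                t["leaf_count"].to_numpy(float),
            ]
        )
        return cls(Z, labels=labels)

    def to_newick(self) -> str:
        """Newick string; internal-node labels carry the node id and height.

        Branch lengths are parent-to-child height differences, so root-to-leaf
        path lengths equal the root height.
        """
        L = self.n_leaves
        hp = self.parent_heights()
        hp[self.root] = self.height(self.root)

        # iterative post-order assembly (single-linkage chains can be deep)
        frag: dict[int, str] = {}
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if node < L:
                bl = hp[node]
                frag[node] = f"{self.labels[node]}:{bl:g}"
            elif not expanded:
                stack.append((node, True))
                c1, c2 = self.children(node)
                stack.append((c1, False))
                stack.append((c2, False))
            else:
                c1, c2 = self.children(node)
                bl = hp[node] - self.height(node)
                frag[node] = f"({frag[c2]},{frag[c1]})n{node}_h{self.height(node):g}:{bl:g}"
        return frag[self.root] + ";"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Dendrogram(n_leaves={self.n_leaves}, root_height={self.height(self.root):g})"


def parent_map(tree: Dendrogram) -> dict[int, int]:
    """Functional alias for :meth:`Dendrogram.parent_map`."""
    return tree.parent_map()


def subtree_leaves(tree: Dendrogram, node: int) -> np.ndarray:
    """Functional alias for :meth:`Dendrogram.subtree_leaves`."""
    return tree.subtree_leaves(node)
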