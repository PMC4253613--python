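"""The tightness statistic: relative height gap between a node and its parent.

For a node ``n`` with parent ``P(n)`` in an inversion-free tree,

    S(n) = (h(P(n)) - h(n)) / h(P(n))

lies in [0, 1]: it is 1 for leaves (h = 0) and 0 when a node merges at its
parent's height.  Because it is a *relative* gap, branches that are well
separated at very different dissimilarity scales can be equally tight, which
is what makes the statistic comparable across the whole tree.

A children-based alternative, defined for any internal node ``n`` with
children ``c1, c2``,

    S2(n) = (h(n) - max(h(c1), h(c2))) / h(n)

is also provided (it covers the root, which has no parent).  The degenerate
case of an all-zero-height tree (all observations identical) yields S = 0 by
convention: no branch can be distinct within identical data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tree import Dendrogram

__all__ = ["tightness_parent", "tightness_children", "tightness_all"]

STATISTICS = ("parent", "children")


def tightness_parent(tree: Dendrogram, node: int) -> float:
    """Tightness of ``node`` relative to its parent; 1 for leaves."""
    if node == tree.root:
        raise ValueError("the root has no parent and therefore no tightness")
    pm = tree.parent_map()
    hp = tree.height(pm[node])
    h = tree.height(node)
    if hp == 0.0:
        return 0.0
    return (hp - h) / hp


def tightness_children(tree: Dendrogram, node: int) -> float:
    """Children-based tightness of an internal node."""
    if tree.is_leaf(node):
        raise ValueError("children-based tightness is defined for internal nodes only")
    h = tree.height(node)
    if h == 0.0:
        return 0.0
    c1, c2 = tree.children(node)
    return (h - max(tree.height(c1), tree.height(c2))) / h


def tightness_all(tree: Dendrogram, statistic: str = "parent") -> pd.DataFrame:
    """Tightness of every eligible internal node.

    ``statistic="parent"`` covers every internal node except the root
    (``L - 2`` rows); ``statistic="children"`` covers every internal node
    including the root (``L - 1`` rows).  Columns: node_id, leaf_count, S.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    L = tree.n_leaves
    heights = tree.Z[:, 2]
    counts = tree.Z[:, 3].astype(int)
    node_ids = np.arange(L, 2 * L - 1)
    if statistic == "parent":
        hp = tree.parent_heights()[L:]
        keep = node_ids != tree.root
        node_ids, counts, heights, hp = node_ids[keep], counts[keep], heights[keep], hp[keep]
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(hp > 0, (hp - heights) / hp, 0.0)
    else:
        hmax = _max_child_heights(tree)
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(heights > 0, (heights - hmax) / heights, 0.0)
    return pd.DataFrame({"node_id": node_ids, "leaf_count": counts, "S": S})


def _max_child_heights(tree: Dendrogram) -> np.ndarray:
    """Taller child height for each internal node (leaves count as height 0)."""
    L = tree.n_leaves
    c = tree.Z[:, :2].astype(int)
    h_all = np.concatenate([np.zeros(L), tree.Z[:, 2]])
    return np.maximum(h_all[c[:, 0]], h_all[c[:, 1]])
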