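"""Extraction of the most detailed significant partition of a tree.

A partition of the observations is *significant* at threshold alpha when
(a) every part is a branch (the full leaf set of one tree node) and (b) for
every part, at least one child of the part's parent node has corrected
tightness p-value strictly below alpha.  Among the significant partitions
the most detailed one — the one with the most parts — is extracted by the
recursion

    can_split(n) = has_significant_child(n)
                   or (can_split(c1) and can_split(c2))

descending from the root through nodes with can_split true; the frontier
reached is the partition.  The second disjunct is what the definition
permits: a node both of whose children are split into smaller parts is not
itself the parent of any part, so it carries no significance requirement of
its own.  Any valid set of split nodes is contained in the can_split set,
which makes the extracted partition maximal.  Leaves can be parts but are
never themselves significant (their tightness is identically 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import Dendrogram

__all__ = ["Partition", "significant_children", "most_detailed_partition", "partition_labels"]


@dataclass
class Partition:
    """A partition of the leaves into branches of a tree."""

    part_roots: list[int]
    parts: list[np.ndarray]  # leaf-id arrays, parallel to part_roots
    alpha: float | None = None
    is_significant: bool = True

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def labels(self, n_leaves: int | None = None) -> np.ndarray:
        """Integer part id per leaf; ids ordered by each part's smallest leaf, from 1."""
        if n_leaves is None:
            n_leaves = sum(len(p) for p in self.parts)
        order = np.argsort([int(p.min()) for p in self.parts])
        out = np.empty(n_leaves, dtype=int)
        for rank, idx in enumerate(order, start=1):
            out[self.parts[idx]] = rank
        return out


def significant_children(tree: Dendrogram, sig: pd.DataFrame, alpha: float) -> set[int]:
    """Nodes with at least one child whose corrected p-value is below alpha.

    Leaf children never qualify; membership is by strict inequality.
    """
    p = dict(zip(sig["node_id"].to_numpy(int), sig["p_corrected"].to_numpy(float)))
    pm = tree.parent_map()
    out: set[int] = set()
    for node, p_node in p.items():
        if p_node < alpha and node in pm:
            out.add(pm[node])
    return out


def most_detailed_partition(tree: Dendrogram, sig: pd.DataFrame, alpha: float = 0.05) -> Partition:
    """The significant partition with the largest number of parts.

    Returns the trivial one-part partition with ``is_significant=False`` when
    no partition into more than one branch is significant at ``alpha``.
    """
    splitters = significant_children(tree, sig, alpha)
    L = tree.n_leaves

    # can_split bottom-up over internal nodes (merge order is bottom-up)
    can_split = np.zeros(tree.n_nodes, dtype=bool)
    for node in range(L, tree.n_nodes):
        c1, c2 = tree.children(node)
        can_split[node] = (node in splitters) or (can_split[c1] and can_split[c2])

    if not can_split[tree.root]:
        return Partition(
            part_roots=[tree.root],
            parts=[np.arange(L)],
            alpha=alpha,
            is_significant=False,
        )

    part_roots: list[int] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if can_split[node]:
            stack.extend(tree.children(node))
        else:
            part_roots.append(node)
    part_roots.sort()
    parts = [tree.subtree_leaves(r) for r in part_roots]
    return Partition(part_roots=part_roots, parts=parts, alpha=alpha, is_significant=True)


def partition_labels(partition: Partition, obs_labels) -> dict[str, int]:
    """Map observation label -> part id (part ids ordered by smallest leaf index)."""
    n = sum(len(p) for p in partition.parts)
    if len(obs_labels) != n:
        raise ValueError(
            f"{len(obs_labels)} observation labels given for a partition of {n} leaves"
        )
    ids = partition.labels(n)
    return {str(lab): int(ids[i]) for i, lab in enumerate(obs_labels)}
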