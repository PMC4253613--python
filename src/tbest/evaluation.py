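"""Agreement between computed partitions and a reference labeling.

The Rand index counts pairs of objects on which two partitions agree
(co-clustered in both or separated in both) out of all C(n,2) pairs.  The
corrected-for-chance Rand index (cRI) is the Hubert-Arabie adjustment,
which subtracts the expected number of concordant pairs under random
assignment of objects to parts of the given sizes and rescales so that
chance agreement scores 0 and identity scores 1.

Because every part found on a tree is necessarily a branch, while the true
classes need not be, perfect recovery of the truth may be impossible on a
given tree.  The *best branch partition* — the partition into branches that
maximizes cRI against the truth — sets the attainable ceiling, and the
*relative cRI* of a computed partition is its cRI divided by that ceiling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .partition import Partition
from .tree import Dendrogram

__all__ = [
    "rand_index",
    "corrected_rand",
    "count_branch_partitions",
    "enumerate_branch_partitions",
    "best_branch_partition",
    "relative_cri",
]


def _as_codes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def _contingency(l1: np.ndarray, l2: np.ndarray) -> np.ndarray:
    c1, c2 = _as_codes(l1), _as_codes(l2)
    n1, n2 = c1.max() + 1, c2.max() + 1
    table = np.zeros((n1, n2), dtype=np.int64)
    np.add.at(table, (c1, c2), 1)
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


def rand_index(labels1, labels2) -> float:
    """Fraction of object pairs on which the two partitions agree."""
    l1, l2 = np.asarray(labels1), np.asarray(labels2)
    if l1.shape != l2.shape:
        raise ValueError("partitions are over different object sets")
    n = l1.shape[0]
    table = _contingency(l1, l2)
    n_pairs = n * (n - 1) // 2
    same_both = _comb2(table).sum()
    same_1 = _comb2(table.sum(axis=1)).sum()
    same_2 = _comb2(table.sum(axis=0)).sum()
    # concordant = co-clustered in both + separated in both
    concordant = n_pairs + 2 * same_both - same_1 - same_2
    return float(concordant / n_pairs)


def corrected_rand(labels1, labels2) -> float:
    """Hubert-Arabie adjusted Rand index.

    1 for identical partitions, expectation 0 for independent random
    partitions with the given part sizes.  The degenerate case where both
    partitions carry no pair information (both one-part or both
    all-singletons, so the adjustment denominator vanishes) returns 1 when
    the partitions are identical and 0 otherwise.
    """
    l1, l2 = np.asarray(labels1), np.asarray(labels2)
    if l1.shape != l2.shape:
        raise ValueError("partitions are over different object sets")
    n = l1.shape[0]
    table = _contingency(l1, l2)
    sum_ij = _comb2(table).sum()
    a = _comb2(table.sum(axis=1)).sum()
    b = _comb2(table.sum(axis=0)).sum()
    n_pairs = n * (n - 1) // 2
    expected = a * b / n_pairs if n_pairs else 0.0
    denom = 0.5 * (a + b) - expected
    if denom == 0:
        return 1.0 if np.array_equal(_as_codes(l1), _as_codes(l2)) else 0.0
    return float((sum_ij - expected) / denom)


# -- branch partitions ------------------------------------------------------


def count_branch_partitions(tree: Dendrogram, node: int | None = None) -> int:
    """Number of distinct partitions of the subtree's leaves into branches.

    Satisfies N(leaf) = 1 and N(node) = 1 + N(c1) * N(c2).
    """
    if node is None:
        node = tree.root
    counts = np.ones(tree.n_nodes, dtype=object)
    for n in range(tree.n_leaves, tree.n_nodes):
        c1, c2 = tree.children(n)
        counts[n] = 1 + counts[c1] * counts[c2]
    return int(counts[node])


def enumerate_branch_partitions(tree: Dendrogram):
    """Yield every branch partition of the tree as a sorted tuple of part roots."""

    memo: dict[int, list[tuple[int, ...]]] = {}

    def frontiers(node: int) -> list[tuple[int, ...]]:
        if node in memo:
            return memo[node]
        if tree.is_leaf(node):
            result = [(node,)]
        else:
            c1, c2 = tree.children(node)
            result = [(node,)]
            for f1, f2 in itertools.product(frontiers(c1), frontiers(c2)):
                result.append(tuple(sorted(f1 + f2)))
        memo[node] = result
        return result

    yield from frontiers(tree.root)


def _frontier_labels(tree: Dendrogram, roots) -> np.ndarray:
    labels = np.empty(tree.n_leaves, dtype=int)
    for i, r in enumerate(roots):
        labels[tree.subtree_leaves(r)] = i
    return labels


def _random_frontier(tree: Dendrogram, rng: np.random.Generator, p_split: float = 0.5) -> list[int]:
    roots: list[int] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if not tree.is_leaf(node) and rng.random() < p_split:
            stack.extend(tree.children(node))
        else:
            roots.append(node)
    return sorted(roots)


def _greedy_best(
    tree: Dendrogram, truth: np.ndarray, rng: np.random.Generator, n_restarts: int = 10
) -> tuple[list[int], float]:
    """Split/merge hill climbing over branch frontiers, with random restarts."""
    pm = tree.parent_map()
    best_roots, best_score = [tree.root], corrected_rand(
        _frontier_labels(tree, [tree.root]), truth
    )
    starts: list[list[int]] = [[tree.root], sorted(tree.children(tree.root))]
    starts += [_random_frontier(tree, rng) for _ in range(n_restarts)]
    for start in starts:
        roots = list(start)
        score = corrected_rand(_frontier_labels(tree, roots), truth)
        improved = True
        while improved:
            improved = False
            best_move, best_move_score = None, score
            current = set(roots)
            for r in roots:  # split moves
                if tree.is_leaf(r):
                    continue
                cand = [x for x in roots if x != r] + list(tree.children(r))
                s = corrected_rand(_frontier_labels(tree, cand), truth)
                if s > best_move_score:
                    best_move, best_move_score = cand, s
            seen_parents = set()
            for r in roots:  # merge moves (both siblings on the frontier)
                parent = pm.get(r)
                if parent is None or parent in seen_parents:
                    continue
                seen_parents.add(parent)
                c1, c2 = tree.children(parent)
                if c1 in current and c2 in current:
                    cand = [x for x in roots if x not in (c1, c2)] + [parent]
                    s = corrected_rand(_frontier_labels(tree, cand), truth)
                    if s > best_move_score:
                        best_move, best_move_score = cand, s
            if best_move is not None:
                roots, score = sorted(best_move), best_move_score
                current = set(roots)
                improved = True
        if score > best_score:
            best_roots, best_score = sorted(roots), score
    return best_roots, best_score


def best_branch_partition(
    tree: Dendrogram,
    truth,
    enumeration_cap: int = 200_000,
    seed: int | None = 0,
) -> tuple[Partition, float, bool]:
    """Branch partition of the tree that best matches the truth by cRI.

    Exhaustive when the number of branch partitions is at most
    ``enumeration_cap``; otherwise greedy split/merge hill climbing from
    several starting frontiers (the third return value flags the heuristic).

    Returns ``(partition, cri, exact)``.
    """
    truth = _as_codes(truth)
    if truth.shape[0] != tree.n_leaves:
        raise ValueError("truth labeling does not cover the tree's leaves")
    if count_branch_partitions(tree) <= enumeration_cap:
        best_roots, best_score = None, -np.inf
        for roots in enumerate_branch_partitions(tree):
            s = corrected_rand(_frontier_labels(tree, roots), truth)
            if s > best_score:
                best_roots, best_score = list(roots), s
        exact = True
    else:
        rng = np.random.default_rng(seed)
        best_roots, best_score = _greedy_best(tree, truth, rng)
        exact = False
    parts = [tree.subtree_leaves(r) for r in best_roots]
    return (
        Partition(part_roots=sorted(best_roots), parts=parts, alpha=None, is_significant=True),
        float(best_score),
        exact,
    )


def relative_cri(computed_labels, truth, best_labels) -> float:
    """cRI of the computed partition relative to the best branch partition's cRI.

    Returns NaN when the ceiling is not positive (no branch partition beats
    chance, so the ratio is undefined).
    """
    ceiling = corrected_rand(best_labels, truth)
    if ceiling <= 0:
        return float("nan")
    return corrected_rand(computed_labels, truth) / ceiling
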