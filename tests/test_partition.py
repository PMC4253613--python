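import itertools

import numpy as np
import pandas as pd
import pytest

from tbest.evaluation import enumerate_branch_partitions
from tbest.tree import Dendrogram
from tbest.partition import (
    most_detailed_partition,
    partition_labels,
    significant_children,
)

from conftest import random_tree


def sig_frame(tree, p_by_node):
    """Significance table stub: corrected p per internal non-root node."""
    rows = [
        {"node_id": n, "leaf_count": tree.leaf_count(n), "S": 0.5, "p_corrected": p}
        for n, p in p_by_node.items()
    ]
    return pd.DataFrame(rows)


def default_ps(tree, fill=1.0):
    return {n: fill for n in tree.internal_nodes if n != tree.root}


class TestSignificantChildren:
    def test_no_significant_nodes(self, four_leaf_tree):
        sig = sig_frame(four_leaf_tree, default_ps(four_leaf_tree))
        assert significant_children(four_leaf_tree, sig, 0.05) == set()

    def test_single_significant_child_marks_parent(self, four_leaf_tree):
        ps = default_ps(four_leaf_tree)
        ps[4] = 0.01  # child of the root
        sig = sig_frame(four_leaf_tree, ps)
        assert significant_children(four_leaf_tree, sig, 0.05) == {four_leaf_tree.root}

    def test_strict_inequality_at_alpha(self, four_leaf_tree):
        ps = default_ps(four_leaf_tree)
        ps[4] = 0.05
        sig = sig_frame(four_leaf_tree, ps)
        assert significant_children(four_leaf_tree, sig, 0.05) == set()


class TestMostDetailedPartition:
    def test_one_significant_sibling_splits_root(self, four_leaf_tree):
        ps = {4: 0.01, 5: 0.5}
        part = most_detailed_partition(four_leaf_tree, sig_frame(four_leaf_tree, ps), 0.05)
        assert part.is_significant and part.n_parts == 2
        assert [p.tolist() for p in part.parts] == [[0, 1], [2, 3]]

    def test_nothing_significant_gives_trivial_partition(self, four_leaf_tree):
        part = most_detailed_partition(
            four_leaf_tree, sig_frame(four_leaf_tree, default_ps(four_leaf_tree)), 0.05
        )
        assert not part.is_significant
        assert part.n_parts == 1 and part.part_roots == [four_leaf_tree.root]

    def test_both_disjuncts_at_root_give_four_parts(self, balanced_eight_tree):
        # all four depth-2 nodes significant; neither mid node is, yet the root
        # splits because both its children are themselves split
        ps = default_ps(balanced_eight_tree)
        for n in (8, 9, 10, 11):
            ps[n] = 0.001
        part = most_detailed_partition(
            balanced_eight_tree, sig_frame(balanced_eight_tree, ps), 0.05
        )
        assert part.n_parts == 4
        assert part.part_roots == [8, 9, 10, 11]

    def test_leaf_parts_allowed(self):
        # chain tree: root joins leaf 3 with the significant branch {0,1,2},
        # so the singleton {3} is a legitimate part
        Z = np.array([[0, 1, 1.0, 2], [2, 4, 2.0, 3], [3, 5, 3.0, 4]])
        t = Dendrogram(Z)
        part = most_detailed_partition(t, sig_frame(t, {4: 0.5, 5: 0.01}), 0.05)
        assert part.n_parts == 2
        assert sorted(p.tolist() for p in part.parts) == [[0, 1, 2], [3]]

    def test_pair_nodes_with_leaf_children_never_split(self):
        # even when every testable node is significant, pairs of leaves stay
        # intact: a leaf child can never be the required significant child
        t = random_tree(seed=0, n_obs=5)
        part = most_detailed_partition(t, sig_frame(t, default_ps(t, fill=0.001)), 0.05)
        assert part.is_significant
        assert all(t.leaf_count(r) <= 2 for r in part.part_roots)

    @pytest.mark.parametrize("seed", range(6))
    def test_validity_audit(self, seed):
        """Every returned part's parent node has a child with p < alpha (a
        part's parent cannot have been split via the both-children-split
        disjunct, because the part itself is unsplit)."""
        t = random_tree(seed=seed, n_obs=12)
        rng = np.random.default_rng(seed)
        ps = {n: p for n, p in zip(default_ps(t), rng.uniform(0, 0.2, t.n_leaves - 2))}
        part = most_detailed_partition(t, sig_frame(t, ps), 0.05)
        if not part.is_significant:
            return
        pm = t.parent_map()
        for r in part.part_roots:
            assert any(ps.get(c, 1.0) < 0.05 for c in t.children(pm[r]))

    @pytest.mark.parametrize("seed", range(6))
    def test_maximality_against_exhaustive_enumeration(self, seed):
        """No valid significant branch partition has more parts than the one
        extracted (brute force over all branch partitions of a small tree)."""
        t = random_tree(seed=seed + 50, n_obs=9)
        rng = np.random.default_rng(seed)
        ps = {n: p for n, p in zip(default_ps(t), rng.uniform(0, 0.15, t.n_leaves - 2))}
        sig = sig_frame(t, ps)
        alpha = 0.08
        part = most_detailed_partition(t, sig, alpha)
        pm = t.parent_map()
        best = 1
        for roots in enumerate_branch_partitions(t):
            if len(roots) == 1:
                continue
            # in an enumerated candidate every element is a part, so the
            # significant-child clause applies to each part's parent
            valid = all(
                any(ps.get(c, 1.0) < alpha for c in t.children(pm[r])) for r in roots
            )
            if valid:
                best = max(best, len(roots))
        if part.is_significant:
            assert part.n_parts == best
        else:
            assert best == 1

    def test_alpha_monotonicity(self):
        """Raising alpha only refines the partition (never merges parts)."""
        t = random_tree(seed=17, n_obs=14)
        rng = np.random.default_rng(17)
        ps = {n: p for n, p in zip(default_ps(t), rng.uniform(0, 0.3, t.n_leaves - 2))}
        sig = sig_frame(t, ps)
        prev = None
        for alpha in (0.01, 0.05, 0.1, 0.2, 0.4):
            part = most_detailed_partition(t, sig, alpha)
            labels = part.labels(t.n_leaves)
            if prev is not None:
                # every current part must be a subset of some previous part
                for pid in np.unique(labels):
                    members = np.flatnonzero(labels == pid)
                    assert len(set(prev[members])) == 1
            prev = labels


class TestPartitionLabels:
    def test_examples(self, four_leaf_tree):
        part = most_detailed_partition(
            four_leaf_tree, sig_frame(four_leaf_tree, {4: 0.001, 5: 0.5}), 0.05
        )
        assert partition_labels(part, ["a", "b", "c", "d"]) == {"a": 1, "b": 1, "c": 2, "d": 2}

    def test_single_part(self, four_leaf_tree):
        part = most_detailed_partition(
            four_leaf_tree, sig_frame(four_leaf_tree, default_ps(four_leaf_tree)), 0.05
        )
        labels = partition_labels(part, list("abcd"))
        assert set(labels.values()) == {1}

    def test_label_count_mismatch(self, four_leaf_tree):
        part = most_detailed_partition(
            four_leaf_tree, sig_frame(four_leaf_tree, default_ps(four_leaf_tree)), 0.05
        )
        with pytest.raises(ValueError, match="labels"):
            partition_labels(part, ["a", "b"])
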