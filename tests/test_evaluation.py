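import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from tbest.evaluation import (
    best_branch_partition,
    corrected_rand,
    count_branch_partitions,
    enumerate_branch_partitions,
    rand_index,
    relative_cri,
)
from tbest.tree import Dendrogram

from conftest import random_tree


def brute_force_rand(l1, l2):
    n = len(l1)
    conc = sum(
        (l1[i] == l1[j]) == (l2[i] == l2[j])
        for i, j in itertools.combinations(range(n), 2)
    )
    return conc / (n * (n - 1) // 2)


def brute_force_cri(l1, l2):
    """Pair counting + hypergeometric expectation, straight from the definition."""
    n = len(l1)

    def comb2(x):
        return x * (x - 1) // 2

    pairs11 = sum(
        (l1[i] == l1[j]) and (l2[i] == l2[j])
        for i, j in itertools.combinations(range(n), 2)
    )
    a = sum(comb2(np.sum(np.asarray(l1) == v)) for v in set(l1))
    b = sum(comb2(np.sum(np.asarray(l2) == v)) for v in set(l2))
    npairs = comb2(n)
    exp = a * b / npairs
    denom = 0.5 * (a + b) - exp
    if denom == 0:
        return 1.0 if len(set(zip(l1, l2))) == max(len(set(l1)), len(set(l2))) else 0.0
    return (pairs11 - exp) / denom


class TestRandIndex:
    def test_identical(self):
        assert rand_index([1, 1, 2, 2], [5, 5, 7, 7]) == 1.0

    def test_crossed_pairs(self):
        assert rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(2 / 6)

    def test_all_singletons(self):
        assert rand_index([1, 2, 3], [7, 8, 9]) == 1.0

    def test_mismatched_sets(self):
        with pytest.raises(ValueError):
            rand_index([1, 2], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        l1, l2 = rng.integers(0, 4, 15), rng.integers(0, 3, 15)
        assert rand_index(l1, l2) == pytest.approx(brute_force_rand(l1, l2))


class TestCorrectedRand:
    def test_identical_nontrivial(self):
        assert corrected_rand([1, 1, 2, 2], [3, 3, 4, 4]) == 1.0

    def test_crossed_pairs_value(self):
        assert corrected_rand([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_degenerate_pairs(self):
        assert corrected_rand([1, 1, 1], [2, 2, 2]) == 1.0
        assert corrected_rand([1, 2, 3], [4, 5, 6]) == 1.0
        assert corrected_rand([1, 1, 1], [1, 2, 3]) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        l1, l2 = rng.integers(0, 3, 20), rng.integers(0, 5, 20)
        assert corrected_rand(l1, l2) == pytest.approx(corrected_rand(l2, l1))

    def test_independent_partitions_center_on_zero(self):
        rng = np.random.default_rng(4)
        vals = [
            corrected_rand(rng.integers(0, 3, 40), rng.integers(0, 3, 40))
            for _ in range(300)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_brute_force_and_sklearn_oracle(self):
        """Hubert-Arabie formula agrees with direct pair counting and with the
        reference library implementation to near machine precision."""
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(5, 25))
            l1 = rng.integers(0, int(rng.integers(2, 5)), n)
            l2 = rng.integers(0, int(rng.integers(2, 5)), n)
            ours = corrected_rand(l1, l2)
            assert ours == pytest.approx(brute_force_cri(l1, l2), abs=1e-12)
            assert ours == pytest.approx(adjusted_rand_score(l1, l2), abs=1e-12)


class TestBranchPartitions:
    def test_count_recursion(self, four_leaf_tree, balanced_eight_tree):
        assert count_branch_partitions(four_leaf_tree) == 5
        assert count_branch_partitions(balanced_eight_tree) == 26

    def test_enumeration_matches_count(self):
        t = random_tree(seed=3, n_obs=8)
        parts = list(enumerate_branch_partitions(t))
        assert len(parts) == count_branch_partitions(t)
        assert len(set(parts)) == len(parts)

    def test_every_partition_covers_leaves(self, balanced_eight_tree):
        for roots in enumerate_branch_partitions(balanced_eight_tree):
            leaves = np.concatenate(
                [balanced_eight_tree.subtree_leaves(r) for r in roots]
            )
            assert sorted(leaves.tolist()) == list(range(8))


class TestBestBranchPartition:
    def test_truth_realizable_as_branches(self, four_leaf_tree):
        part, cri, exact = best_branch_partition(four_leaf_tree, [0, 0, 1, 1])
        assert exact and cri == 1.0
        assert part.part_roots == [4, 5]

    def test_unrealizable_three_class_truth(self, four_leaf_tree):
        truth = [0, 1, 2, 2]
        part, cri, exact = best_branch_partition(four_leaf_tree, truth)
        assert exact
        best = max(
            corrected_rand(
                np.concatenate(
                    [[i] * four_leaf_tree.leaf_count(r) for i, r in enumerate(roots)]
                )[np.argsort(np.concatenate([four_leaf_tree.subtree_leaves(r) for r in roots]))],
                truth,
            )
            for roots in enumerate_branch_partitions(four_leaf_tree)
        )
        assert cri == pytest.approx(best)

    def test_constant_truth_gives_one_part(self, four_leaf_tree):
        part, cri, exact = best_branch_partition(four_leaf_tree, [0, 0, 0, 0])
        assert part.part_roots == [four_leaf_tree.root] and cri == 1.0

    def test_never_beaten_by_random_branch_partitions(self):
        t = random_tree(seed=8, n_obs=10)
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, 10)
        _, best_cri, exact = best_branch_partition(t, truth)
        assert exact
        all_parts = list(enumerate_branch_partitions(t))
        idx = rng.integers(0, len(all_parts), 2000)
        for i in idx:
            labels = np.empty(10, dtype=int)
            for j, r in enumerate(all_parts[i]):
                labels[t.subtree_leaves(r)] = j
            assert corrected_rand(labels, truth) <= best_cri + 1e-12

    def test_heuristic_finds_realizable_truth(self):
        t = random_tree(seed=12, n_obs=20)
        c1, c2 = t.children(t.root)
        truth = np.empty(20, dtype=int)
        truth[t.subtree_leaves(c1)] = 0
        truth[t.subtree_leaves(c2)] = 1
        part, cri, exact = best_branch_partition(t, truth, enumeration_cap=5)
        assert not exact
        assert cri == pytest.approx(1.0)


class TestRelativeCri:
    def test_computed_equals_best(self):
        truth = [0, 0, 1, 1]
        assert relative_cri([5, 5, 6, 6], truth, [1, 1, 2, 2]) == pytest.approx(1.0)

    def test_trivial_computed_scores_zero(self):
        truth = [0, 0, 1, 1]
        assert relative_cri([1, 1, 1, 1], truth, [1, 1, 2, 2]) == 0.0

    def test_coarser_than_best_lands_inside_unit_interval(self):
        truth = [0, 0, 1, 1, 2, 2]
        best = [0, 0, 1, 1, 2, 2]
        coarser = [0, 0, 1, 1, 1, 1]
        assert 0 < relative_cri(coarser, truth, best) < 1

    def test_undefined_ceiling_returns_nan(self):
        truth = [0, 1, 0, 1]
        assert np.isnan(relative_cri([0, 0, 1, 1], truth, [0, 0, 1, 1]))
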