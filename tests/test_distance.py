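"""LSAP reduction, Hungarian solver, and partition distance vs oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from meanpartition import (
    GraphState,
    Partition,
    augment_step,
    brute_force_distance,
    hungarian,
    partition_distance,
    reduce_direct,
    reduce_fast,
)
from meanpartition.errors import (
    IncompatiblePartitionsError,
    NothingToAugmentError,
)


def permutation_min_cost(matrix: np.ndarray) -> int:
    """Exhaustive LSAP oracle: minimum over all C! permutations."""
    n = matrix.shape[0]
    return min(sum(matrix[i, perm[i]] for i in range(n))
               for perm in itertools.permutations(range(n)))


class TestReduction:
    def test_worked_pair_cost_matrix(self, worked_pair):
        p1, p2 = worked_pair
        assert reduce_direct(p1, p2).matrix.tolist() == [[1, 2], [2, 0]]

    def test_identical_partitions_zero_diagonal(self, rng, random_partition):
        p = random_partition(20, 5, rng)
        cm = reduce_direct(p, p)
        assert (np.diag(cm.matrix) == 0).all()

    def test_padding_columns_cost_cluster_size(self):
        # 3 singletons vs one big cluster: one real column of zeros,
        # padding columns cost |a_i| = 1
        cm = reduce_direct(Partition([0, 1, 2]), Partition([0, 0, 0]))
        assert cm.matrix.tolist() == [[0, 1, 1], [0, 1, 1], [0, 1, 1]]
        assert cm.n_real_cols == 1

    def test_padding_rows_cost_zero(self):
        cm = reduce_fast(Partition([0, 0, 0]), Partition([0, 1, 2]))
        assert cm.size == 3
        assert (cm.matrix[1:] == 0).all()

    def test_singleton_vs_singleton(self):
        assert reduce_fast(Partition([0]), Partition([0])).matrix.tolist() == [[0]]

    def test_row_sum_invariant(self, rng, random_partition):
        # sum_j (|a_i| - c(i,j)) = |a_i| over real columns
        p1 = random_partition(40, 6, rng)
        p2 = random_partition(40, 6, rng)
        cm = reduce_fast(p1, p2)
        real = cm.matrix[:cm.n_real_rows, :cm.n_real_cols]
        sizes = cm.row_sizes[:cm.n_real_rows]
        assert ((sizes[:, None] - real).sum(axis=1) == sizes).all()
        assert (real <= sizes[:, None]).all() and (real >= 0).all()

    @given(st.lists(st.integers(0, 9), min_size=1, max_size=50),
           st.lists(st.integers(0, 9), min_size=1, max_size=50))
    @settings(max_examples=300, deadline=None)
    def test_fast_equals_direct_bit_exact(self, raw1, raw2):
        n = min(len(raw1), len(raw2))
        p1, p2 = Partition(raw1[:n]), Partition(raw2[:n])
        assert np.array_equal(reduce_fast(p1, p2).matrix,
                              reduce_direct(p1, p2).matrix)

    def test_mismatched_n_raises(self):
        with pytest.raises(IncompatiblePartitionsError):
            reduce_fast(Partition([0, 1]), Partition([0, 1, 1]))
        with pytest.raises(IncompatiblePartitionsError):
            reduce_direct(Partition([0, 1]), Partition([0, 1, 1]))


class TestHungarian:
    def test_worked_matrix(self):
        m, state = hungarian(np.array([[1, 2], [2, 0]]))
        assert m.assignment.tolist() == [0, 1]
        assert m.total_cost == 1
        state.assert_invariants()

    @pytest.mark.parametrize("size", [1, 3, 6])
    def test_zero_matrix(self, size):
        m, _ = hungarian(np.zeros((size, size), dtype=int))
        assert m.total_cost == 0

    def test_random_matrices_vs_permutation_oracle(self, rng):
        for _ in range(60):
            c = int(rng.integers(1, 8))
            a = rng.integers(0, 30, size=(c, c))
            m, state = hungarian(a)
            assert m.total_cost == permutation_min_cost(a)
            assert m.total_cost == state.total_potential()

    def test_vs_scipy_on_larger_matrices(self, rng):
        for _ in range(30):
            c = int(rng.integers(2, 16))
            a = rng.integers(0, 50, size=(c, c))
            m, _ = hungarian(a)
            r, cc = linear_sum_assignment(a)
            assert m.total_cost == int(a[r, cc].sum())

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            hungarian(np.zeros((2, 3), dtype=int))
        with pytest.raises(ValueError):
            hungarian(np.array([[-1, 0], [0, 0]]))
        with pytest.raises(TypeError):
            hungarian(np.zeros((2, 2), dtype=float))


class TestAugmentStep:
    def test_single_step_on_zero_matrix_matches_one_pair(self):
        state = GraphState(np.zeros((3, 3), dtype=int))
        augment_step(state)
        assert (state.match_row >= 0).sum() == 1

    def test_tight_path_requires_no_dual_update(self):
        # an unmatched worker with a tight edge to an unmatched job:
        # the path is reversed without ever computing delta
        state = GraphState(np.array([[0, 5], [5, 0]]))
        y_before = (state.y_rows.copy(), state.y_cols.copy())
        augment_step(state)
        assert np.array_equal(state.y_rows, y_before[0])
        assert np.array_equal(state.y_cols, y_before[1])
        assert state.match_row[0] == 0

    def test_invariants_after_every_step_and_final_cost(self, rng):
        for _ in range(40):
            c = int(rng.integers(1, 13))
            a = rng.integers(0, 25, size=(c, c))
            state = GraphState(a)
            for step in range(c):
                augment_step(state)
                state.assert_invariants()
                assert (state.match_row >= 0).sum() == step + 1
            # total cost of the matching is the sum of all potentials
            cost = int(a[np.arange(c), state.match_row].sum())
            assert cost == state.total_potential()
            assert cost == permutation_min_cost(a) if c <= 7 else True

    def test_c_steps_reproduce_hungarian(self, rng):
        a = rng.integers(0, 9, size=(5, 5))
        state = GraphState(a)
        for _ in range(5):
            augment_step(state)
        m, _ = hungarian(a)
        assert state.total_potential() == m.total_cost

    def test_nothing_to_augment(self):
        state = GraphState(np.zeros((2, 2), dtype=int))
        augment_step(state)
        augment_step(state)
        with pytest.raises(NothingToAugmentError):
            augment_step(state)


class TestPartitionDistance:
    def test_worked_examples(self, worked_pair):
        p1, p2 = worked_pair
        assert partition_distance(p1, p2) == 1
        assert partition_distance(p1, p1) == 0
        assert partition_distance(Partition([0, 1, 2, 3]),
                                  Partition([0, 0, 0, 0])) == 3

    def test_agrees_with_brute_force(self, rng, random_partition):
        for _ in range(300):
            n = int(rng.integers(2, 30))
            p1 = random_partition(n, 6, rng)
            p2 = random_partition(n, 6, rng)
            assert partition_distance(p1, p2) == brute_force_distance(p1, p2)

    def test_metric_properties(self, rng, random_partition):
        for _ in range(100):
            n = int(rng.integers(2, 25))
            a, b, c = (random_partition(n, 7, rng) for _ in range(3))
            dab = partition_distance(a, b)
            assert dab == partition_distance(b, a)
            assert partition_distance(a, a) == 0
            assert dab + partition_distance(b, c) >= partition_distance(a, c)
            assert 0 <= dab <= n - 1

    def test_mismatched_n_raises(self):
        with pytest.raises(IncompatiblePartitionsError):
            partition_distance(Partition([0, 1]), Partition([0, 1, 1]))


class TestBruteForce:
    def test_single_cluster_row(self):
        # C1 = 1: keep the largest overlap, delete the rest
        p1 = Partition([0] * 6)
        p2 = Partition([0, 0, 0, 1, 1, 2])
        assert brute_force_distance(p1, p2) == 6 - 3

    def test_symmetric(self, rng, random_partition):
        for _ in range(30):
            p1 = random_partition(12, 5, rng)
            p2 = random_partition(12, 5, rng)
            assert brute_force_distance(p1, p2) == brute_force_distance(p2, p1)

    def test_guard_on_many_clusters(self):
        p = Partition(list(range(9)))
        with pytest.raises(ValueError):
            brute_force_distance(p, p)
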