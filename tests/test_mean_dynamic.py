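"""Dynamic graph states: row updates, snapshots, and classic equivalence."""

import numpy as np
import pytest

from meanpartition import (
    Partition,
    PosteriorSample,
    approximate_mean,
    approximate_mean_dynamic,
    init_states,
    partition_distance,
    propose_move,
    restore,
    sample_crp,
    make_posterior,
)
from meanpartition.errors import EmptySampleError, InconsistentStateError


class TestInitStates:
    def test_identical_candidate_gives_zero_distances(self):
        p = Partition([0, 0, 1, 1, 2])
        states = init_states(p, PosteriorSample([p] * 3))
        assert [s.distance for s in states] == [0, 0, 0]

    def test_worked_pair_distance(self, worked_pair):
        p1, p2 = worked_pair
        (state,) = init_states(p2, PosteriorSample([p1]))
        assert state.distance == partition_distance(p1, p2) == 1

    def test_random_states_match_from_scratch(self, rng, random_sample,
                                              random_partition):
        sample = random_sample(25, 8, 5, rng)
        cand = random_partition(25, 4, rng)
        for state, p in zip(init_states(cand, sample), sample.partitions):
            assert state.distance == partition_distance(p, cand)
            state.assert_invariants()

    def test_spare_empty_column_always_present(self, rng, random_partition):
        cand = random_partition(10, 3, rng)
        (state,) = init_states(cand, PosteriorSample([random_partition(10, 2, rng)]))
        assert state.size >= cand.n_clusters + 1


class TestProposeMove:
    def test_worked_move_reaches_distance_zero(self, worked_pair):
        # moving element 2 of candidate p2 into cluster {0,1} makes the
        # candidate equal to sample p1
        p1, p2 = worked_pair
        (state,) = init_states(p2, PosteriorSample([p1]))
        d, _ = propose_move(state, 2, 1, 0)
        assert d == 0
        state.assert_invariants()

    def test_move_away_from_identical_candidate_costs_one(self):
        p = Partition([0, 0, 1, 1])
        (state,) = init_states(p, PosteriorSample([p]))
        d, _ = propose_move(state, 0, 0, 1)
        assert d == 1

    def test_move_to_new_cluster_via_spare_column(self):
        p = Partition([0, 0, 0, 1, 1])
        (state,) = init_states(p, PosteriorSample([p]))
        d, _ = propose_move(state, 0, 0, 2)  # spare column index == C
        assert d == 1

    def test_costs_never_decrease(self, rng, random_partition):
        cand = random_partition(15, 4, rng)
        (state,) = init_states(cand, PosteriorSample([random_partition(15, 4, rng)]))
        before = state.cost.copy()
        p = 3
        propose_move(state, p, int(cand.labels[p]),
                     (int(cand.labels[p]) + 1) % cand.n_clusters)
        assert (state.cost >= before).all()

    def test_noop_and_inconsistent_moves_rejected(self, worked_pair):
        p1, p2 = worked_pair
        (state,) = init_states(p2, PosteriorSample([p1]))
        with pytest.raises(ValueError):
            propose_move(state, 2, 1, 1)
        with pytest.raises(InconsistentStateError):
            propose_move(state, 2, 0, 1)  # element 2 is in cluster 1, not 0

    def test_random_move_sequences_match_from_scratch(self, rng):
        """Commit/reject sequences: every reported distance is exact and
        every restore is bit-identical to the pre-move state."""
        for _ in range(15):
            n = int(rng.integers(8, 40))
            base = sample_crp(n, 1.5, seed=rng)
            if base.n_clusters < 2:
                continue
            k = int(rng.integers(2, 6))
            sample = make_posterior(base, k, 2, seed=rng)
            cand = base.labels.copy()
            states = init_states(cand, sample)
            n_clusters = base.n_clusters
            for _move in range(12):
                p = int(rng.integers(n))
                e2 = int(cand[p])
                # avoid births/deaths: move between existing clusters only,
                # from clusters of size >= 2
                if (cand == e2).sum() < 2:
                    continue
                t = int(rng.integers(n_clusters))
                if t == e2:
                    continue
                snaps = []
                before = [s.copy() for s in states]
                for s, part in zip(states, sample.partitions):
                    d, snap = propose_move(s, p, e2, t)
                    snaps.append(snap)
                    s.assert_invariants()
                    cand[p] = t
                    assert d == partition_distance(part, Partition(cand))
                    cand[p] = e2
                if rng.random() < 0.5:  # commit
                    cand[p] = t
                else:  # reject: bit-exact restore
                    for s, snap, b in zip(states, snaps, before):
                        restore(s, snap)
                        assert s.equals(b)


class TestRestore:
    def test_roundtrip_is_bit_identical(self, worked_pair):
        p1, p2 = worked_pair
        (state,) = init_states(p2, PosteriorSample([p1]))
        before = state.copy()
        _, snap = propose_move(state, 2, 1, 0)
        restore(state, snap)
        assert state.equals(before)
        assert state.distance == before.distance

    def test_restore_twice_raises(self, worked_pair):
        p1, p2 = worked_pair
        (state,) = init_states(p2, PosteriorSample([p1]))
        _, snap = propose_move(state, 2, 1, 0)
        restore(state, snap)
        with pytest.raises(InconsistentStateError):
            restore(state, snap)

    def test_stale_snapshot_raises(self, worked_pair):
        p1, p2 = worked_pair
        (state,) = init_states(p2, PosteriorSample([p1]))
        _, snap1 = propose_move(state, 2, 1, 0)
        restore(state, snap1)
        _, snap2 = propose_move(state, 2, 1, 0)
        _ = snap2
        with pytest.raises(InconsistentStateError):
            restore(state, snap1)


class TestDynamicMean:
    def test_identical_copies(self):
        p = Partition([0, 1, 1, 2])
        res = approximate_mean_dynamic(PosteriorSample([p] * 3))
        assert res.mean == p and res.objective == 0.0

    def test_empty_sample_raises(self):
        with pytest.raises(EmptySampleError):
            PosteriorSample([])

    @pytest.mark.parametrize("kwargs", [
        {},
        {"exponent": 1},
        {"best_of_row": True},
        {"init": "singletons"},
        {"strategy": "case-analysis"},
    ])
    def test_equivalent_to_classic_under_identical_config(self, rng, kwargs):
        """The dynamic engine is an acceleration, not an approximation
        change: identical move trace, final partition and objective."""
        for _ in range(4):
            n = int(rng.integers(8, 22))
            base = sample_crp(n, 1.2, seed=rng)
            if base.n_clusters < 2:
                continue
            sample = make_posterior(base, int(rng.integers(2, 7)), 2, seed=rng)
            rc = approximate_mean(sample, **kwargs)
            rd = approximate_mean_dynamic(sample, verify=True, **kwargs)
            assert rc.moves == rd.moves
            assert rc.objective == rd.objective
            assert rc.mean == rd.mean

    def test_per_move_objectives_match_full_recomputation(self, rng):
        # verify=True cross-checks every proposed distance from scratch
        base = sample_crp(20, 1.0, seed=rng)
        if base.n_clusters < 2:
            base = Partition(np.arange(20) % 3)
        sample = make_posterior(base, 5, 3, seed=rng)
        res = approximate_mean_dynamic(sample, verify=True, init="singletons")
        objs = [m.objective for m in res.moves]
        assert all(a > b for a, b in zip(objs, objs[1:]))
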