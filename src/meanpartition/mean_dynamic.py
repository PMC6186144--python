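"""Accelerated mean-partition search with dynamically maintained graphs.

Instead of recomputing K partition distances from scratch for every
candidate move, one Hungarian :class:`~meanpartition.distance.GraphState`
is maintained per sample partition.  Moving element ``p`` from candidate
cluster ``E2`` (column ``j``) to ``D2`` (column ``k``) changes a single row
``i`` of each cost matrix — the row of ``p``'s cluster ``C1`` in that sample
partition: ``c(i, j)`` grows by one (``p`` leaves ``E2``) and ``c(i, k)``
shrinks by one (``p`` joins ``D2``).  To preserve dual feasibility the
decrement is never applied; the whole row is shifted up by one instead and
one is subtracted from the reported distance, so stored costs only ever
increase.  The matching edge of ``C1`` is then removed and a single
Hungarian augmentation step rematches it — ``O(C^2)`` per candidate move
instead of a full ``O(C^3 + N)`` distance computation.  A rejected move is
undone from an ``O(C)`` row snapshot.

The scan order, acceptance rule and termination condition are identical to
:func:`meanpartition.mean_classic.approximate_mean`; the dynamic engine is
an acceleration, not a change of method, and under identical configuration
both produce the same move trace, final partition and objective.

The always-offered empty target cluster is represented as a guaranteed
spare padded column (cost ``|a_i|`` per row), so moving an element into a
new cluster is an ordinary row update.  When an accepted move creates a new
candidate cluster or empties an old one, the matrix shape changes and all K
states are rebuilt from scratch; such events are rare (at most C per cycle)
and keep the row-update argument exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import MeanConfig, initial_candidate, weighted_objective
from .distance import GraphState, _cost_matrix_arrays, augment_step, hungarian
from .errors import InconsistentStateError
from .mean_classic import _distances_to_sample, _make_config
from .partitions import Partition
from .sample import MeanResult, MoveRecord, PosteriorSample

__all__ = ["RowSnapshot", "init_states", "propose_move", "restore",
           "approximate_mean_dynamic"]


@dataclass
class RowSnapshot:
    """O(C) record sufficient to undo one proposed move on one graph.

    One row of costs changes per move, and one augmentation touches at most
    O(C) matching edges and the full potential vector (itself O(C)), so a
    bit-exact restore fits in the O(C) budget.
    """

    row: int
    row_costs: np.ndarray
    y_rows: np.ndarray
    y_cols: np.ndarray
    match_row: np.ndarray
    match_col: np.ndarray
    row_offset: int
    revision: int
    used: bool = field(default=False)


def init_states(candidate, sample: PosteriorSample) -> list[GraphState]:
    """Build one fully solved graph state per sample partition.

    ``candidate`` may be a :class:`Partition` or a compact label array; the
    array is shared (not copied) across states so the engine can keep it
    current in place.  Each state's ``distance`` equals the from-scratch
    partition distance between its sample partition and the candidate.
    """
    if isinstance(candidate, Partition):
        cand = candidate.labels.copy()
    else:
        cand = np.asarray(candidate, dtype=np.int64)
    n_clusters = int(cand.max()) + 1
    states = []
    for p in sample.partitions:
        if p.n_elements != cand.shape[0]:
            raise InconsistentStateError(
                "candidate and sample have different element counts")
        cm = _cost_matrix_arrays(p.labels, p.n_clusters, cand, n_clusters,
                                 extra_cols=1)  # spare empty-target column
        _, state = hungarian(cm)
        state.sample_labels = p.labels
        state.candidate_labels = cand
        states.append(state)
    return states


def propose_move(state: GraphState, p: int, e2: int, d2: int) -> tuple[int, RowSnapshot]:
    """Apply the row update for moving ``p`` from column ``e2`` to ``d2``.

    Mutates ``state`` in place (single-row cost shift, unmatch of ``p``'s
    sample cluster, one augmentation) and returns the new reported distance
    together with the snapshot that undoes it.  The returned distance equals
    the from-scratch partition distance to the moved candidate.
    """
    if e2 == d2:
        raise ValueError("move target equals source cluster (no-op)")
    if state.sample_labels is None:
        raise InconsistentStateError("state carries no sample partition labels")
    if state.candidate_labels is not None and int(state.candidate_labels[p]) != e2:
        raise InconsistentStateError(
            f"element {p} is not in candidate cluster {e2}")
    row = int(state.sample_labels[p])
    snap = RowSnapshot(
        row=row,
        row_costs=state.cost[row].copy(),
        y_rows=state.y_rows.copy(),
        y_cols=state.y_cols.copy(),
        match_row=state.match_row.copy(),
        match_col=state.match_col.copy(),
        row_offset=int(state.row_offsets[row]),
        revision=state.revision,
    )
    # row shift: +1 everywhere except the target column, +1 extra on the
    # source column; stored costs never decrease, the uniform +1 is paid
    # back by the final "decrement the result by one" via row_offsets.
    state.cost[row] += 1
    state.cost[row, d2] -= 1
    state.cost[row, e2] += 1
    state.row_offsets[row] += 1
    # the matched edge of C1 may no longer be tight: unmatch and rematch
    c2 = int(state.match_row[row])
    state.match_row[row] = -1
    state.match_col[c2] = -1
    augment_step(state)
    state.revision += 1
    return int(state.distance), snap


def restore(state: GraphState, snap: RowSnapshot) -> GraphState:
    """Undo the immediately preceding :func:`propose_move`, bit-exactly."""
    if snap.used or state.revision != snap.revision + 1:
        raise InconsistentStateError("snapshot is stale or already restored")
    state.cost[snap.row] = snap.row_costs
    state.y_rows[:] = snap.y_rows
    state.y_cols[:] = snap.y_cols
    state.match_row[:] = snap.match_row
    state.match_col[:] = snap.match_col
    state.row_offsets[snap.row] = snap.row_offset
    state.revision = snap.revision
    snap.used = True
    return state


def approximate_mean_dynamic(sample: PosteriorSample,
                             config: MeanConfig | None = None,
                             **overrides) -> MeanResult:
    """Approximate the mean partition with dynamically maintained graphs.

    Same contract as :func:`meanpartition.mean_classic.approximate_mean`;
    with ``strategy="case-analysis"`` candidate moves are first screened by
    the cost-change case predictor and the graphs are only touched when a
    move is accepted.
    """
    from . import costchange  # deferred: costchange depends only on distance

    cfg = _make_config(config, overrides)
    cand = initial_candidate(sample, cfg).copy()
    slabels = [p.labels for p in sample.partitions]
    scounts = [p.n_clusters for p in sample.partitions]
    weights = sample.weights
    n = sample.n_elements
    n_clusters = int(cand.max()) + 1
    kk = sample.k

    states = init_states(cand, sample)
    dists = np.array([s.distance for s in states], dtype=np.int64)
    obj = weighted_objective(dists, weights, cfg.exponent)

    def verify_distances(p: int, e2: int, t: int, nd: np.ndarray) -> None:
        cand[p] = t
        fresh = _distances_to_sample(
            cand, max(n_clusters, t + 1), slabels, scounts)
        cand[p] = e2
        if not np.array_equal(fresh, nd):
            raise InconsistentStateError(
                f"dynamic distances {nd.tolist()} != from-scratch {fresh.tolist()}")

    def evaluate(p: int, e2: int, t: int) -> np.ndarray:
        """Propose the move on all K states, record distances, undo."""
        nd = np.empty(kk, dtype=np.int64)
        snaps = []
        for k, st in enumerate(states):
            d, snap = propose_move(st, p, e2, t)
            nd[k] = d
            snaps.append(snap)
        for st, snap in zip(states, snaps):
            restore(st, snap)
        if cfg.verify:
            verify_distances(p, e2, t, nd)
        return nd

    def commit(p: int, e2: int, t: int) -> np.ndarray:
        nd = np.empty(kk, dtype=np.int64)
        for k, st in enumerate(states):
            nd[k], _ = propose_move(st, p, e2, t)
        return nd

    moves: list[MoveRecord] = []
    cycles = 0
    converged = False
    while cycles < cfg.max_cycles:
        cycles += 1
        changed = False
        for p in range(n):
            e2 = int(cand[p])
            sizes = np.bincount(cand, minlength=n_clusters)
            targets = [c for c in range(n_clusters) if c != e2]
            if sizes[e2] > 1:
                targets.append(n_clusters)  # the spare empty-target column
            best_target = -1
            best_obj = obj
            for t in targets:
                if cfg.strategy == "case-analysis":
                    res = costchange.screened_move_evaluation(
                        states, p, e2, t, weights, dists, cfg.exponent,
                        threshold=best_obj)
                    if res is costchange.ABANDONED:
                        continue
                    cand_obj = weighted_objective(res, weights, cfg.exponent)
                    if cfg.verify:
                        nd_oracle = evaluate(p, e2, t)
                        if not np.array_equal(nd_oracle, res):
                            raise InconsistentStateError(
                                "case-analysis prediction disagrees with rematch")
                else:
                    nd = evaluate(p, e2, t)
                    cand_obj = weighted_objective(nd, weights, cfg.exponent)
                if cand_obj < best_obj:
                    best_target, best_obj = t, cand_obj
                    if not cfg.best_of_row:
                        break
            if best_target >= 0:
                t = best_target
                nd = commit(p, e2, t)
                cand_obj = weighted_objective(nd, weights, cfg.exponent)
                if cand_obj != best_obj:  # same integers -> same float
                    raise InconsistentStateError(
                        "committed objective disagrees with evaluation")
                cand[p] = t
                birth = t == n_clusters
                death = (not birth) and not (cand == e2).any()
                obj = cand_obj
                moves.append(MoveRecord(p, e2, t, obj))
                changed = True
                if birth:
                    n_clusters += 1
                elif death:
                    cand[cand > e2] -= 1
                    n_clusters -= 1
                if birth or death:
                    # matrix shape (or column identity) changed: rebuild
                    states = init_states(cand, sample)
                    dists = np.array([s.distance for s in states],
                                     dtype=np.int64)
                    if not np.array_equal(dists, nd):
                        raise InconsistentStateError(
                            "rebuilt distances disagree with committed move")
                else:
                    dists = nd
        if not changed:
            converged = True
            break

    return MeanResult(mean=Partition(cand), objective=obj, cycles=cycles,
                      moves=moves, converged=converged, algorithm="dynamic",
                      strategy=cfg.strategy)
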