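"""Predicting a move's per-graph cost change from the current graph.

For a candidate move of element ``p`` from cluster ``E2`` to ``D2``, each
sample graph's distance changes by exactly -1, 0 or +1.  Instead of
performing the row update and augmentation, the change can be read off the
current graph by case analysis on the tight-edge structure.  Write ``C1``
for ``p``'s cluster in the sample partition (a worker row) and ``C2`` for
the job currently matched to ``C1``.

Case A (``E2 != C2``) — the matched edge of ``C1`` does not get more
expensive; the change is -1 if ``D2 == C2``, or if the edge ``(C1, D2)`` is
tight and ``C2`` is reachable from ``D2`` over tight edges (the path can be
reversed for free); otherwise 0.  A cost increase is impossible: the old
matching remains valid at unchanged cost.

Case B (``E2 == C2``) — the matched edge itself gets more expensive:

* B.3.1: ``(C1, D2)`` tight and a ``D2 -> C2`` path exists -> -1;
* any tight ``C1 -> C2`` path exists -> 0 (it re-tightens after a unit
  potential increase on ``C1``);
* B.3.3: ``(C1, D2)`` tight after a unit potential increase (slack exactly
  1) and a ``D2 -> C2`` path exists -> 0;
* B.3.2: ``(C1, D2)`` tight but no ``D2 -> C2`` path — undecided from
  reachability alone; :func:`resolve_B32` settles it by slack inspection;
* B.3.4 / B.3.5 (slack of ``(C1, D2)`` is 1 with no ``D2 -> C2`` path, or
  at least 2) -> +1.

Reachability is answered by breadth-first search over the current tight
edges (non-matched edges directed worker -> job, matched edges job ->
worker), ``O(C^2)`` worst case, and B.3.2 by direct slack inspection over
the two bridging reachable sets.

Screening: while evaluating a move across the K graphs, the decided
predictions give an optimistic total (undecided graphs counted as 0, their
best case).  If that optimistic total already fails to beat the best local
change found so far, the move is abandoned without resolving any B.3.2
graph; otherwise undecided graphs are resolved one at a time, re-checking
the bound after each.  Since a B.3.2 resolution can never return -1,
abandoning never discards an improving move, and the accepted move sequence
is identical to unscreened evaluation.
"""

from __future__ import annotations

import numpy as np

from .config import MeanConfig, weighted_objective
from .distance import GraphState
from .errors import InconsistentStateError
from .sample import PosteriorSample

__all__ = ["UNDECIDED_B32", "ABANDONED", "predict_cost_change",
           "resolve_B32", "screened_move_evaluation", "audit_predictions"]


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: Returned by :func:`predict_cost_change` when sub-case B.3.2 applies and
#: the slack-based question must be settled by :func:`resolve_B32`.
UNDECIDED_B32 = _Sentinel("UNDECIDED_B32")

#: Returned by :func:`screened_move_evaluation` when the screening bound
#: proves the move cannot beat the best local change found so far.
ABANDONED = _Sentinel("ABANDONED")


def _forward_reach(state: GraphState, slack: np.ndarray,
                   start_col: int) -> tuple[set, set]:
    """Workers and jobs reachable from job ``start_col`` over tight edges."""
    cols = {start_col}
    rows: set[int] = set()
    queue = [start_col]
    while queue:
        c = queue.pop()
        r = int(state.match_col[c])
        if r < 0 or r in rows:
            continue
        rows.add(r)
        for nc in np.flatnonzero(slack[r] == 0):
            nc = int(nc)
            if nc != c and nc not in cols:
                cols.add(nc)
                queue.append(nc)
    return rows, cols


def _backward_reach(state: GraphState, slack: np.ndarray,
                    target_col: int) -> tuple[set, set]:
    """Workers and jobs with a tight-edge path *to* job ``target_col``."""
    cols = {target_col}
    rows: set[int] = set()
    queue = [target_col]
    while queue:
        c = queue.pop()
        for r in np.flatnonzero(slack[:, c] == 0):
            r = int(r)
            if int(state.match_row[r]) == c or r in rows:
                continue  # matched edge points job -> worker, unusable here
            rows.add(r)
            pc = int(state.match_row[r])
            if pc >= 0 and pc not in cols:
                cols.add(pc)
                queue.append(pc)
    return rows, cols


def _col_reaches_col(state: GraphState, slack: np.ndarray,
                     c_from: int, c_to: int) -> bool:
    _, cols = _forward_reach(state, slack, c_from)
    return c_to in cols


def _row_reaches_col(state: GraphState, slack: np.ndarray,
                     row: int, c_to: int) -> bool:
    matched = int(state.match_row[row])
    for c in np.flatnonzero(slack[row] == 0):
        c = int(c)
        if c == matched:
            continue
        if c == c_to or _col_reaches_col(state, slack, c, c_to):
            return True
    return False


def _move_context(state: GraphState, p: int, e2: int, d2: int):
    if e2 == d2:
        raise ValueError("move target equals source cluster (no-op)")
    if state.sample_labels is None:
        raise InconsistentStateError("state carries no sample partition labels")
    if state.candidate_labels is not None and int(state.candidate_labels[p]) != e2:
        raise InconsistentStateError(f"element {p} is not in candidate cluster {e2}")
    row = int(state.sample_labels[p])
    c2 = int(state.match_row[row])
    if c2 < 0:
        raise InconsistentStateError("graph state has no perfect matching")
    return row, c2


def predict_cost_change(state: GraphState, p: int, e2: int, d2: int):
    """Predict the distance change of moving ``p`` from ``e2`` to ``d2``.

    Returns -1, 0 or +1, or :data:`UNDECIDED_B32` when sub-case B.3.2
    applies.  The state is not modified.
    """
    row, c2 = _move_context(state, p, e2, d2)
    slack = state.slack()
    if e2 != c2:  # Case A
        if d2 == c2:
            return -1
        if slack[row, d2] == 0 and _col_reaches_col(state, slack, d2, c2):
            return -1
        return 0
    # Case B
    s = int(slack[row, d2])
    d2_to_c2 = _col_reaches_col(state, slack, d2, c2) if s <= 1 else False
    if s == 0 and d2_to_c2:
        return -1  # B.3.1
    if _row_reaches_col(state, slack, row, c2):
        return 0  # a C1 -> C2 path re-tightens after a unit increase on C1
    if s == 1 and d2_to_c2:
        return 0  # B.3.3
    if s == 0:
        return UNDECIDED_B32  # B.3.2
    return 1  # B.3.4 / B.3.5


def resolve_B32(state: GraphState, p: int, e2: int, d2: int) -> int:
    """Settle sub-case B.3.2: does a path appear after a unit potential increase?

    Collects the workers reachable from ``D2`` and the jobs that co-reach
    ``C2`` over tight edges and looks for a bridging worker-job pair of
    slack exactly one; such an edge becomes tight after one dual update and
    splices the two sets into a ``D2 -> C2`` path (cost change 0).  With no
    slack-1 bridge at least two dual updates are needed and the cost rises
    by one.  A slack-0 bridge would contradict B.3.2 and raises.
    """
    if predict_cost_change(state, p, e2, d2) is not UNDECIDED_B32:
        raise InconsistentStateError("resolve_B32 called on a non-B.3.2 move")
    row, c2 = _move_context(state, p, e2, d2)
    slack = state.slack()
    workers, _ = _forward_reach(state, slack, d2)
    _, jobs_co = _backward_reach(state, slack, c2)
    sub = slack[np.ix_(sorted(workers), sorted(jobs_co))]
    if (sub == 0).any():
        raise InconsistentStateError(
            "slack-0 bridge in a B.3.2 state (contradicts no D2->C2 path)")
    return 0 if (sub == 1).any() else 1


def screened_move_evaluation(states, p: int, e2: int, d2: int,
                             weights, distances, exponent: int,
                             threshold: float):
    """Evaluate a move across all K graphs with CC_best/L_best screening.

    Returns the vector of predicted new distances, or :data:`ABANDONED`
    when the optimistic bound (undecided B.3.2 graphs counted as their best
    case, 0) already reaches ``threshold`` — the best local objective found
    so far — in which case no B.3.2 graph is resolved.
    """
    distances = np.asarray(distances, dtype=np.int64)
    new_d = distances.copy()
    undecided: list[int] = []
    for k, st in enumerate(states):
        pred = predict_cost_change(st, p, e2, d2)
        if pred is UNDECIDED_B32:
            undecided.append(k)
        else:
            new_d[k] += pred
    for idx, k in enumerate(undecided):
        # optimistic bound: remaining undecided graphs kept at +0
        if weighted_objective(new_d, weights, exponent) >= threshold:
            return ABANDONED
        new_d[k] += resolve_B32(states[k], p, e2, d2)
    if undecided and weighted_objective(new_d, weights, exponent) >= threshold:
        return ABANDONED
    return new_d


def audit_predictions(sample: PosteriorSample,
                      config: MeanConfig | None = None,
                      **overrides) -> dict:
    """Replay a dynamic mean run, checking every prediction against reality.

    Runs the first-improving local search with rematch semantics; before
    each proposed move the case predictor is consulted, then the move is
    actually proposed (and restored if rejected) and the predicted and
    actual distance deltas are tallied.  Returns agreement statistics.
    """
    from .config import initial_candidate
    from .mean_classic import _make_config
    from .mean_dynamic import init_states, propose_move, restore

    cfg = _make_config(config, overrides)
    cand = initial_candidate(sample, cfg).copy()
    n = sample.n_elements
    n_clusters = int(cand.max()) + 1
    weights = sample.weights
    states = init_states(cand, sample)
    dists = np.array([s.distance for s in states], dtype=np.int64)
    obj = weighted_objective(dists, weights, cfg.exponent)

    stats = {"proposals": 0, "decided": 0, "undecided": 0, "agreements": 0,
             "mismatches": 0, "case_a": 0, "case_b": 0,
             "b32_zero": 0, "b32_plus_one": 0}

    for _ in range(cfg.max_cycles):
        changed = False
        for p in range(n):
            e2 = int(cand[p])
            sizes = np.bincount(cand, minlength=n_clusters)
            targets = [c for c in range(n_clusters) if c != e2]
            if sizes[e2] > 1:
                targets.append(n_clusters)
            for t in targets:
                preds = []
                for st in states:
                    row = int(st.sample_labels[p])
                    in_case_a = int(st.match_row[row]) != e2
                    pred = predict_cost_change(st, p, e2, t)
                    stats["proposals"] += 1
                    stats["case_a" if in_case_a else "case_b"] += 1
                    if pred is UNDECIDED_B32:
                        stats["undecided"] += 1
                        pred = resolve_B32(st, p, e2, t)
                        stats["b32_zero" if pred == 0 else "b32_plus_one"] += 1
                    else:
                        stats["decided"] += 1
                    preds.append(pred)
                nd = np.empty(len(states), dtype=np.int64)
                snaps = []
                for k, st in enumerate(states):
                    nd[k], snap = propose_move(st, p, e2, t)
                    snaps.append(snap)
                deltas = nd - dists
                for pred, actual in zip(preds, deltas):
                    if pred == actual:
                        stats["agreements"] += 1
                    else:
                        stats["mismatches"] += 1
                cand_obj = weighted_objective(nd, weights, cfg.exponent)
                if cand_obj < obj:
                    cand[p] = t
                    birth = t == n_clusters
                    death = (not birth) and not (cand == e2).any()
                    obj = cand_obj
                    changed = True
                    if birth:
                        n_clusters += 1
                    elif death:
                        cand[cand > e2] -= 1
                        n_clusters -= 1
                    if birth or death:
                        states = init_states(cand, sample)
                        dists = np.array([s.distance for s in states],
                                         dtype=np.int64)
                    else:
                        dists = nd
                    break
                for st, snap in zip(states, snaps):
                    restore(st, snap)
        if not changed:
            break
    return stats
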