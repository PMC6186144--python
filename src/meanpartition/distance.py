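"""Partition distance via LSAP reduction and a primal-dual Hungarian solver.

The partition distance ``D(A, B)`` is the minimum number of elements that
must be removed from both partitions so that the remainders are equal.  It
equals the optimum of a linear sum assignment problem over the cluster pair
costs ``c(i, j) = |a_i \\ b_j| = |a_i| - |a_i & b_j|``: a minimum-cost
one-to-one matching of clusters of ``A`` onto clusters of ``B``.

Two reductions build the cost matrix:

* :func:`reduce_direct` — per-cluster-pair intersection counting, ``O(N*C^2)``;
* :func:`reduce_fast`  — per-element billing, ``O(C^2 + N)``: start every
  counter at zero, give each element a discount of one on the single cluster
  pair that contains it, then add ``|a_i|`` to every cell of row ``i``.

Both produce bit-identical matrices; the fast variant is what the distance
and mean computations use.

The Hungarian solver keeps the explicit machinery that the dynamic mean
algorithm later manipulates: a bipartite graph of workers (rows, set S) and
jobs (columns, set T), node potentials ``y`` with the dual-feasibility
invariants

1. every node is adjacent to at most one matched (T->S) edge,
2. ``y(i) + y(j) = c(i, j)`` on every edge of the tight-edge graph,
3. ``y(i) + y(j) <= c(i, j)`` for every pair,

and augmentation steps that alternate breadth-first reachability searches
with dual updates by ``delta = min slack`` over reachable workers and
non-reachable jobs.  At termination the matching cost is the sum of all
potentials.  This is the ``O(C^4)`` formulation; matrices here are small
(C is the cluster count, typically ``C << N``), and the explicit state is
the point: the dynamic mean updates it in place.

Costs are integers throughout, so every oracle comparison is bit-exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from collections import deque

import numpy as np

from .errors import NothingToAugmentError
from .partitions import Partition, canonicalize, _require_same_n

__all__ = [
    "CostMatrix",
    "Matching",
    "GraphState",
    "reduce_direct",
    "reduce_fast",
    "hungarian",
    "augment_step",
    "partition_distance",
    "brute_force_distance",
]


@dataclass(frozen=True)
class CostMatrix:
    """Square integer LSAP cost matrix with padding bookkeeping.

    ``matrix[i, j]`` is ``|a_i| - |a_i & b_j|`` for real rows/columns.  When
    the two partitions have different cluster counts the matrix is padded
    with empty clusters: an empty row costs 0 in every column
    (``|{} \\ b_j| = 0``) and an empty column costs ``|a_i|`` in row ``i``
    (``|a_i \\ {}| = |a_i|``).  ``row_sizes[i] = |a_i|`` (0 on padding rows).
    """

    matrix: np.ndarray
    row_sizes: np.ndarray
    n_real_rows: int
    n_real_cols: int

    @property
    def size(self) -> int:
        return int(self.matrix.shape[0])


@dataclass(frozen=True)
class Matching:
    """A perfect matching: bijection row -> column plus its total cost."""

    assignment: np.ndarray
    total_cost: int

    def __post_init__(self):
        a = np.asarray(self.assignment)
        if sorted(a.tolist()) != list(range(a.shape[0])):
            raise ValueError("assignment is not a bijection on 0..C-1")


def _cost_matrix_arrays(labels1: np.ndarray, n1: int,
                        labels2: np.ndarray, n2: int,
                        extra_cols: int = 0) -> CostMatrix:
    """Fast reduction working directly on label arrays.

    ``extra_cols`` forces at least ``n2 + extra_cols`` columns before
    squaring; the dynamic mean uses one guaranteed spare (empty) column as
    the always-offered empty target cluster.
    """
    size = max(n1, n2 + extra_cols)
    sizes1 = np.bincount(labels1, minlength=n1).astype(np.int64)
    # per-element billing: discount 1 on the one cluster pair containing it
    cells = np.zeros((n1, n2), dtype=np.int64)
    np.add.at(cells, (labels1, labels2), -1)
    # then add |a_i| to every cell of row i (padding columns included)
    matrix = np.zeros((size, size), dtype=np.int64)
    matrix[:n1, :] = sizes1[:, None]
    matrix[:n1, :n2] += cells
    row_sizes = np.zeros(size, dtype=np.int64)
    row_sizes[:n1] = sizes1
    return CostMatrix(matrix, row_sizes, n1, n2)


def reduce_fast(p1: Partition, p2: Partition, *, extra_cols: int = 0) -> CostMatrix:
    """Build the LSAP cost matrix in ``O(C^2 + N)`` by per-element billing."""
    p1, p2 = canonicalize(p1), canonicalize(p2)
    _require_same_n(p1, p2)
    return _cost_matrix_arrays(p1.labels, p1.n_clusters,
                               p2.labels, p2.n_clusters, extra_cols)


def reduce_direct(p1: Partition, p2: Partition, *, extra_cols: int = 0) -> CostMatrix:
    """Build the LSAP cost matrix by explicit cluster-pair intersections.

    ``O(N * C^2)``; kept as the slow reference the fast reduction is checked
    against.
    """
    p1, p2 = canonicalize(p1), canonicalize(p2)
    _require_same_n(p1, p2)
    n1, n2 = p1.n_clusters, p2.n_clusters
    size = max(n1, n2 + extra_cols)
    matrix = np.zeros((size, size), dtype=np.int64)
    row_sizes = np.zeros(size, dtype=np.int64)
    for i, a in enumerate(p1.clusters):
        row_sizes[i] = len(a)
        for j in range(size):
            if j < n2:
                matrix[i, j] = len(a) - len(a & p2.clusters[j])
            else:
                matrix[i, j] = len(a)  # empty padding column
    return CostMatrix(matrix, row_sizes, n1, n2)


# ---------------------------------------------------------------------------
# Hungarian solver with explicit potentials
# ---------------------------------------------------------------------------

class GraphState:
    """Mutable state of the Hungarian bipartite graph for one cost matrix.

    Holds the (stored) cost matrix, the potentials on workers and jobs, the
    current matching and, for the dynamic mean, per-row cost offsets: the
    dynamic row update only ever *increases* stored costs (a decrement is
    replaced by a uniform +1 row shift whose effect is subtracted from the
    reported distance), so dual feasibility is never violated.

    ``distance`` is only defined while the matching is perfect; it equals
    the sum of all potentials minus the accumulated row offsets.
    """

    __slots__ = ("cost", "row_sizes", "y_rows", "y_cols", "match_row",
                 "match_col", "row_offsets", "revision", "n_real_rows",
                 "n_real_cols", "sample_labels", "candidate_labels")

    def __init__(self, cost):
        if isinstance(cost, CostMatrix):
            matrix = cost.matrix
            self.row_sizes = cost.row_sizes.copy()
            self.n_real_rows = cost.n_real_rows
            self.n_real_cols = cost.n_real_cols
        else:
            matrix = np.asarray(cost)
            if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
                raise ValueError("cost matrix must be square")
            if not np.issubdtype(matrix.dtype, np.integer):
                raise TypeError("cost matrix must be integer-valued")
            if (matrix < 0).any():
                raise ValueError("cost matrix must be non-negative")
            self.row_sizes = matrix.max(axis=1).astype(np.int64)
            self.n_real_rows = self.n_real_cols = matrix.shape[0]
        n = matrix.shape[0]
        self.cost = matrix.astype(np.int64).copy()
        self.y_rows = np.zeros(n, dtype=np.int64)
        self.y_cols = np.zeros(n, dtype=np.int64)
        self.match_row = np.full(n, -1, dtype=np.int64)  # row -> col
        self.match_col = np.full(n, -1, dtype=np.int64)  # col -> row
        self.row_offsets = np.zeros(n, dtype=np.int64)
        self.revision = 0
        self.sample_labels: np.ndarray | None = None
        self.candidate_labels: np.ndarray | None = None

    # -- inspection -------------------------------------------------------

    @property
    def size(self) -> int:
        return int(self.cost.shape[0])

    def slack(self) -> np.ndarray:
        """``c(i, j) - y(i) - y(j)`` for every worker-job pair."""
        return self.cost - self.y_rows[:, None] - self.y_cols[None, :]

    def total_potential(self) -> int:
        return int(self.y_rows.sum() + self.y_cols.sum())

    @property
    def is_perfect(self) -> bool:
        return bool((self.match_row >= 0).all())

    @property
    def distance(self) -> int:
        if not self.is_perfect:
            raise NothingToAugmentError(
                "distance is only defined for a perfect matching")
        return self.total_potential() - int(self.row_offsets.sum())

    def matching(self) -> Matching:
        if not self.is_perfect:
            raise NothingToAugmentError("matching is not perfect yet")
        return Matching(self.match_row.copy(), int(self.total_potential()))

    def assert_invariants(self) -> None:
        """Raise AssertionError unless invariants (1)-(3) hold."""
        slack = self.slack()
        assert (slack >= 0).all(), "invariant (3) violated: negative slack"
        rows = np.flatnonzero(self.match_row >= 0)
        cols = self.match_row[rows]
        assert (slack[rows, cols] == 0).all(), \
            "invariant (2) violated: matched edge not tight"
        # invariant (1): matching arrays are mutually consistent bijections
        assert (self.match_col[cols] == rows).all(), "matching arrays disagree"
        matched_cols = np.flatnonzero(self.match_col >= 0)
        assert matched_cols.shape == rows.shape, "matching arrays disagree"

    def copy(self) -> "GraphState":
        new = GraphState.__new__(GraphState)
        new.cost = self.cost.copy()
        new.row_sizes = self.row_sizes.copy()
        new.y_rows = self.y_rows.copy()
        new.y_cols = self.y_cols.copy()
        new.match_row = self.match_row.copy()
        new.match_col = self.match_col.copy()
        new.row_offsets = self.row_offsets.copy()
        new.revision = self.revision
        new.n_real_rows = self.n_real_rows
        new.n_real_cols = self.n_real_cols
        new.sample_labels = self.sample_labels
        new.candidate_labels = self.candidate_labels
        return new

    def equals(self, other: "GraphState") -> bool:
        """Bit-exact comparison of the algorithmically relevant fields."""
        return (np.array_equal(self.cost, other.cost)
                and np.array_equal(self.y_rows, other.y_rows)
                and np.array_equal(self.y_cols, other.y_cols)
                and np.array_equal(self.match_row, other.match_row)
                and np.array_equal(self.match_col, other.match_col)
                and np.array_equal(self.row_offsets, other.row_offsets))


def _flip_path(state: GraphState, col: int, parent_col: np.ndarray) -> None:
    """Reverse the alternating path ending in unmatched job ``col``."""
    c = col
    while True:
        r = int(parent_col[c])
        prev = int(state.match_row[r])
        state.match_row[r] = c
        state.match_col[c] = r
        if prev < 0:
            break
        c = prev


def augment_step(state: GraphState) -> GraphState:
    """Match exactly one additional worker, preserving invariants (1)-(3).

    Repeats { breadth-first reachability from all unmatched workers over
    tight edges; if an unmatched job is reached, reverse the path; else dual
    update by ``delta`` } until one path reversal happens.  Ties (multiple
    tight augmenting paths) are broken by lowest node index via the BFS
    discovery order, so runs are deterministic.
    """
    n = state.size
    free_rows = np.flatnonzero(state.match_row < 0)
    if free_rows.size == 0:
        raise NothingToAugmentError("no unmatched worker to augment")
    while True:
        slack = state.slack()
        s_reach = np.zeros(n, dtype=bool)
        t_reach = np.zeros(n, dtype=bool)
        parent_col = np.full(n, -1, dtype=np.int64)
        s_reach[free_rows] = True
        queue = deque(int(r) for r in free_rows)
        aug_col = -1
        while queue and aug_col < 0:
            r = queue.popleft()
            matched_c = state.match_row[r]
            for c in np.flatnonzero(slack[r] == 0):
                c = int(c)
                if t_reach[c] or c == matched_c:
                    continue
                t_reach[c] = True
                parent_col[c] = r
                rr = int(state.match_col[c])
                if rr < 0:
                    aug_col = c
                    break
                if not s_reach[rr]:
                    s_reach[rr] = True
                    queue.append(rr)
        if aug_col >= 0:
            _flip_path(state, aug_col, parent_col)
            return state
        # dual update: raise reachable workers, lower reachable jobs
        delta = int(slack[np.ix_(s_reach, ~t_reach)].min())
        state.y_rows[s_reach] += delta
        state.y_cols[t_reach] -= delta


def hungarian(cost) -> tuple[Matching, GraphState]:
    """Solve the LSAP for a square non-negative integer cost matrix.

    Returns the minimum-cost perfect matching together with the final graph
    state (potentials + matching), whose total potential equals the matching
    cost.
    """
    state = GraphState(cost)
    for _ in range(state.size):
        augment_step(state)
    return state.matching(), state


def _lsap_min_cost(cm: CostMatrix) -> int:
    state = GraphState(cm)
    for _ in range(state.size):
        augment_step(state)
    return state.total_potential()


def partition_distance(p1: Partition, p2: Partition) -> int:
    """Minimum number of elements to delete from each partition to equalize them."""
    return int(_lsap_min_cost(reduce_fast(p1, p2)))


_BRUTE_FORCE_MAX_C = 8


def brute_force_distance(p1: Partition, p2: Partition) -> int:
    """Independent oracle: enumerate all injective cluster mappings.

    ``D = N - max over injections of the summed cluster intersections``.
    Guarded to ``max(C1, C2) <= 8``; intended for tests only.
    """
    p1, p2 = canonicalize(p1), canonicalize(p2)
    _require_same_n(p1, p2)
    c = max(p1.n_clusters, p2.n_clusters)
    if c > _BRUTE_FORCE_MAX_C:
        raise ValueError(
            f"brute force guard: max cluster count {c} > {_BRUTE_FORCE_MAX_C}")
    overlap = np.zeros((c, c), dtype=np.int64)
    for i, a in enumerate(p1.clusters):
        for j, b in enumerate(p2.clusters):
            overlap[i, j] = len(a & b)
    best = max(sum(overlap[i, perm[i]] for i in range(c))
               for perm in itertools.permutations(range(c)))
    return int(p1.n_elements - best)
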