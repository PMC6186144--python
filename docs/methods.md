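# Methods

This note documents the model, the algorithms, the numerical choices and
the limitations of `meanpartition` in one place.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Partition distance as an assignment problem

A partition of N elements is stored as a canonical integer label vector:
clusters are numbered 0..C−1 by order of first appearance when scanning
elements 0..N−1.  Canonical numbering makes equality, hashing and file
round trips exact.

The distance D(A, B) between two partitions is the minimum number of
elements that must be removed from both so that the remainders are equal.
Equivalently, over one-to-one matchings of clusters of A onto clusters of
B, it is N minus the maximum achievable summed overlap — a linear sum
assignment problem (LSAP) with integer costs

    c(i, j) = |a_i \ b_j| = |a_i| − |a_i ∩ b_j|.

Two reductions build the cost matrix and are held bit-identical by tests:

* **direct** — count every pairwise intersection, O(N·C²);
* **fast** — one pass over elements: start all counters at zero, subtract
  one from the single cell (cluster-in-A, cluster-in-B) containing each
  element, then add |a_i| to every cell of row i; O(C² + N).

Unequal cluster counts are padded with empty clusters to a square matrix:
an empty row costs 0 everywhere (|∅ \ b_j| = 0) and an empty column costs
|a_i| in row i (|a_i \ ∅| = |a_i|).  Padding provably leaves the optimum
unchanged.

## Hungarian solver

The LSAP is solved by the primal-dual Hungarian method with explicit node
potentials y on workers (rows) and jobs (columns), maintaining

1. every node is adjacent to at most one matched (job→worker) edge;
2. y(i) + y(j) = c(i, j) on every tight edge;
3. y(i) + y(j) ≤ c(i, j) for every pair (dual feasibility),

so that at termination the matching cost equals Σ y.  An *augmentation
step* alternates breadth-first reachability over tight edges (non-matched
edges directed worker→job, matched edges job→worker) with dual updates by
Δ = min slack between reachable workers and unreachable jobs, until one
path reversal matches one more worker.  This is the O(C⁴) formulation; it
was chosen over the slack-cached O(C³) variant because its state is
exactly what the dynamic mean manipulates, and C (the cluster count) is
small in the intended regime — a Dirichlet-process posterior has on the
order of α·log N clusters, so C ≪ N.

All costs, potentials and distances are integers; every oracle comparison
in the tests is bit-exact, with no floating-point tolerance anywhere in
the distance machinery.  Ties (several tight augmenting paths, equal Δ
candidates) are broken by lowest node index via the BFS discovery order,
making every run deterministic.

## Mean partition by local search

The mean of a weighted sample {(P_k, w_k)} minimizes
Σ_k w_k · D(P, P_k)^e with exponent e = 2 by default (e = 1 selectable;
the accepted moves can differ between the two, which is why the choice is
surfaced).  Exact minimization is NP-hard in general, so the estimator is
a first-improvement local search:

* scan elements 0..N−1; for each element consider every existing cluster
  (ascending index) and one empty cluster, offered last;
* accept the first strictly improving move (or, with `best_of_row=True`,
  the best improving move of the row); ties never move;
* stop when a full cycle accepts nothing; `max_cycles` (default 1000)
  guards pathological configurations and flags non-convergence.

The default initial candidate is the sample partition with the lowest
objective — cheap, deterministic, and never worse than the best sample;
all-singletons, all-one-cluster, a seeded Chinese-restaurant draw, and a
user-given partition are selectable.  Duplicate sample partitions are
collapsed into one record with multiplicity weight by default, which
leaves the objective identical and shrinks K.

During the search, cluster ids are kept *stable*: an emptied cluster is
deleted and higher ids shift down by one, but no first-appearance
relabeling happens until the final result is canonicalized.  A cosmetic
relabel mid-search would permute cost-matrix columns and force the dynamic
engine to rebuild all of its graph states after nearly every accepted
move; stable ids avoid that while both engines share the identical
convention, so their move traces stay comparable element for element.

## Dynamic acceleration

One Hungarian graph state is maintained per sample partition, with the
candidate's clusters as columns plus one guaranteed spare empty column
(cost |a_i| per row) representing the always-offered empty target cluster.
Moving element p from candidate cluster E2 (column j) to D2 (column k)
changes one row i — the row of p's cluster in that sample partition:
c(i, j) grows by one and c(i, k) shrinks by one.  Because a cost decrease
could violate dual feasibility, the decrement is never applied: the whole
updated row is shifted up by one instead, the shift is accumulated in a
per-row offset, and the reported distance is Σ y minus the total offset.
The matching edge of row i is then removed and a single augmentation step
rematches it — O(C²) per candidate move instead of a full O(C³ + N)
distance computation.  A rejected move is undone from a snapshot holding
one cost row, the potential vectors, the matching arrays and the row
offset — O(C) data — and restoration is bit-exact (asserted in tests).
Snapshots carry a revision counter; restoring a stale or already-used
snapshot raises.

When an accepted move creates a new candidate cluster or empties an old
one, the matrix shape (or column identity) changes and all K states are
rebuilt from scratch.  Such births and deaths are rare — at most C per
cycle — and the rebuild keeps the row-update argument exactly valid; an
incremental add/remove-column path is a possible future optimization.

## Cost-change case analysis

For a candidate move, each graph's distance changes by exactly −1, 0 or
+1, and the value can be read off the current tight-edge graph without
touching it.  Write C1 for p's cluster-row in the sample partition and C2
for its currently matched column.

* **Case A (E2 ≠ C2)** — the change is −1 if D2 = C2, or if the edge
  (C1, D2) is tight and C2 is reachable from D2 over tight edges;
  otherwise 0.  (+1 is impossible: the old matching stays valid at
  unchanged cost.)
* **Case B (E2 = C2)** — −1 under the same tight-edge-plus-path condition;
  0 if any tight C1→C2 path exists (it re-tightens after a unit potential
  increase on C1) or if slack(C1, D2) = 1 with a D2→C2 path; +1 when
  slack(C1, D2) ≥ 1 with no path; *undecided* when the edge (C1, D2) is
  tight but no D2→C2 path exists (sub-case B.3.2).

B.3.2 is settled by slack inspection: collect the workers reachable from
D2 and the jobs co-reaching C2 over tight edges; the change is 0 exactly
when some bridging worker–job pair has slack 1 (one dual update makes it
tight and splices a D2→C2 path), else +1.  A slack-0 bridge would
contradict B.3.2 and raises.  Only the workers-from-D2 × jobs-to-C2
orientation is inspected: under the edge-direction convention (non-matched
tight edges worker→job, matched edges job→worker) a slack-1 pair in the
transposed orientation creates an edge pointing the wrong way and cannot
contribute a path; this reading is validated against the row-update oracle
on ≥10⁴ randomized instances in the tests and the acceptance script, with
both B.3.2 outcomes exercised.

Reachability is answered by breadth-first search over tight edges, O(C²)
worst case, and the B.3.2 slack search inspects the two reachable sets
directly.  Sub-quadratic alternatives (dynamic transitive closure via fast
matrix multiplication, sorted-slack-matrix searches) are deliberately out
of scope: they only pay off with fast matrix multiplication machinery that
has no practical implementation, while the decision logic — the part worth
testing — is fully exercised by the explicit searches.

While evaluating a move across the K graphs, decided predictions form an
optimistic bound (undecided graphs counted at their best case, 0).  If the
bound already fails to beat the best local change found so far the move is
abandoned without resolving any undecided graph; otherwise undecided
graphs are resolved one at a time, re-checking the bound after each.
Because a B.3.2 resolution can never return −1, abandoning never discards
an improving move, and the screened strategy provably accepts the same
move sequence as the unscreened one (asserted trace-identical in tests).
On acceptance the row updates are actually applied and the realized
distances are required to equal the predictions.

## Synthetic generators

* **RM pairs** (`make_rm_pair`) — a base partition of C clusters of M
  consecutive elements, and a copy in which x distinct elements (sampled
  without replacement) are each moved to a uniformly chosen different
  existing cluster at move time.  No new clusters are created; if earlier
  moves emptied every alternative, an emptied original cluster may be
  revived.  By construction D(P1, P2) ≤ x (moving the same elements back
  equalizes the pair), which the tests assert across the grid C ∈ {2, 5,
  10}, M ∈ {5, 50}.
* **CRP draws** (`sample_crp`) — sequential Chinese-restaurant assignment:
  element t joins an existing cluster c with probability |c|/(t + α) and
  opens a new one with probability α/(t + α).  The expected cluster count
  is exactly Σ_{t=0}^{N−1} α/(α + t) (≈ 5.187 at N = 100, α = 1), the
  finite-N form of the α·log N rule of thumb for Dirichlet-process
  posteriors; the Monte-Carlo mean over 10⁴ draws is checked against the
  exact sum within three standard errors.
* **Noisy posteriors** (`make_posterior`) — K independent copies of a
  known base partition, each perturbed by a fixed number of random element
  moves, unit weights.  This emulates an MCMC posterior concentrated
  around its mode and supports exact-recovery tests (N = 60, three
  balanced clusters, K = 50, two noise moves per copy: the dynamic mean is
  required to recover the base in at least 18 of 20 replicates).

What the generators do **not** emulate: real MCMC draws are autocorrelated
and multi-modal, label-switching-free summaries may be harder when the
posterior has several well-separated modes, and real genetic data induce
cluster-size imbalance and admixed individuals.  Passing the recovery
tests therefore shows the machinery is exact and the consensus is
recoverable under concentrated noise — not that the mean partition is the
right summary for every real posterior.

All generators are bit-reproducible under a fixed seed; every source of
randomness in the package and its scripts flows through an explicit
`numpy.random.Generator`.

## Benchmark design

Absolute runtimes are hardware-bound, so the harness (`run_benchmark`)
reports only classic/dynamic wall-time *ratios* and asserts, in tests,
nothing beyond a monotone trend.  Two modes exist: `fit` times whole
searches; `cycle` first runs the search to convergence (untimed) and then
times one full steady-state scan per engine from the converged mean, so
both engines execute the identical all-rejections proposal sequence and
the measurement isolates the per-move evaluation cost — the quantity in
which the engines differ — from initialization and accepted-move
bookkeeping.  One untimed warmup call per side absorbs first-run effects,
repeats are interleaved (classic, dynamic, classic, …) so machine drift
hits both sides alike, the cyclic garbage collector is paused during timed
sections, and per-side medians are taken.

The trend test uses C = 2, K = 3 and N ∈ {64, 1024, 4096}, pooling times
over three grid replicates before forming each per-size ratio: in a
vectorized implementation the classic engine's O(N) term per candidate
move carries a small constant, so a wide N range is needed before it
visibly dominates the N-free per-move overhead; these sizes keep the full
check under about two minutes on one CPU while leaving the trend
comfortably larger than timing noise.

## Problem sizes used by the checks

The randomized suites run at: 1000 pairs (N ≤ 200, C ≤ 20) for the
reduction; 1000 pairs (max C ≤ 7) plus 500 triples for the distance
oracle and metric properties; 200 matrices (C ≤ 15) for the Hungarian
invariants; 100 move sequences (N ≤ 80, K ≤ 12) for dynamic-state
exactness; 50 random posteriors (N ≤ 28, K ≤ 10) for three-way engine
trace equivalence; ≥10⁴ (state, move) instances for the case ledger; 10⁴
CRP draws for the cluster-count expectation; and 20 replicates of the
recovery setting.  These sizes exercise every code path (including
padding, cluster birth/death rebuilds and B.3.2 resolutions both ways)
while keeping the default test run fast.

## Known limitations

* The local search guarantees a local optimum only; no restarts or
  annealing are built in beyond the selectable initial candidate.
* The dynamic engine rebuilds all K states on candidate cluster birth or
  death rather than editing matrix shape incrementally.
* The Hungarian solver is the O(C⁴) potential formulation; for C beyond a
  few hundred clusters a slack-cached O(C³) solver would be preferable.
* `lines` files cannot carry non-uniform weights (use the JSON format),
  and input labels are canonicalized — original label tokens are not
  round-tripped.
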