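"""Reference mean-partition approximation by full distance recomputation.

The mean (consensus) partition of a weighted sample is approximated by local
search: starting from an initial candidate, scan all elements; for each
element evaluate moving it to every existing cluster plus one empty cluster;
accept a move only if it strictly lowers the weighted objective
``sum_k w_k D(candidate, P_k)^exponent``; stop when a full cycle makes no
change.  Every candidate move is scored by recomputing all K partition
distances from scratch — ``O(N*C*K)`` distance computations per cycle — which
makes this engine the trusted but slow reference that the dynamic engine is
required to reproduce move for move.
"""

from __future__ import annotations

import numpy as np

from .config import MeanConfig, initial_candidate, weighted_objective
from .distance import _cost_matrix_arrays, _lsap_min_cost
from .errors import IncompatiblePartitionsError
from .partitions import Partition, canonicalize
from .sample import MeanResult, MoveRecord, PosteriorSample

__all__ = ["objective", "approximate_mean"]


def _distances_to_sample(labels: np.ndarray, n_clusters: int,
                         sample_labels: list[np.ndarray],
                         sample_n_clusters: list[int]) -> np.ndarray:
    out = np.empty(len(sample_labels), dtype=np.int64)
    for k, (sl, sc) in enumerate(zip(sample_labels, sample_n_clusters)):
        out[k] = _lsap_min_cost(_cost_matrix_arrays(sl, sc, labels, n_clusters))
    return out


def objective(candidate: Partition, sample: PosteriorSample,
              exponent: int = 2) -> float:
    """Weighted objective ``sum_k w_k * D(candidate, P_k)^exponent``."""
    candidate = canonicalize(candidate)
    if candidate.n_elements != sample.n_elements:
        raise IncompatiblePartitionsError(
            "candidate and sample have different element counts")
    dists = _distances_to_sample(
        candidate.labels, candidate.n_clusters,
        [p.labels for p in sample.partitions],
        [p.n_clusters for p in sample.partitions])
    return weighted_objective(dists, sample.weights, exponent)


def approximate_mean(sample: PosteriorSample,
                     config: MeanConfig | None = None,
                     **overrides) -> MeanResult:
    """Approximate the mean partition by full-recomputation local search.

    Keyword overrides are applied on top of ``config`` (or the defaults),
    e.g. ``approximate_mean(sample, exponent=1, init="singletons")``.
    """
    cfg = _make_config(config, overrides)
    labels = initial_candidate(sample, cfg).copy()
    slabels = [p.labels for p in sample.partitions]
    scounts = [p.n_clusters for p in sample.partitions]
    weights = sample.weights
    n = sample.n_elements
    n_clusters = int(labels.max()) + 1

    def score(lab: np.ndarray, c: int) -> float:
        return weighted_objective(
            _distances_to_sample(lab, c, slabels, scounts), weights, cfg.exponent)

    obj = score(labels, n_clusters)
    moves: list[MoveRecord] = []
    cycles = 0
    converged = False
    while cycles < cfg.max_cycles:
        cycles += 1
        changed = False
        for p in range(n):
            e2 = int(labels[p])
            sizes = np.bincount(labels, minlength=n_clusters)
            targets = [c for c in range(n_clusters) if c != e2]
            if sizes[e2] > 1:
                targets.append(n_clusters)  # one empty cluster, offered last
            best_target = -1
            best_obj = obj
            for t in targets:
                labels[p] = t
                cand_obj = score(labels, n_clusters + (1 if t == n_clusters else 0))
                labels[p] = e2
                if cand_obj < best_obj:
                    best_target, best_obj = t, cand_obj
                    if not cfg.best_of_row:
                        break
            if best_target >= 0:
                labels[p] = best_target
                if best_target == n_clusters:
                    n_clusters += 1
                elif not (labels == e2).any():
                    # source cluster died: compact ids, preserving order
                    labels[labels > e2] -= 1
                    n_clusters -= 1
                obj = best_obj
                moves.append(MoveRecord(p, e2, best_target, obj))
                changed = True
        if not changed:
            converged = True
            break

    return MeanResult(mean=Partition(labels), objective=obj, cycles=cycles,
                      moves=moves, converged=converged, algorithm="classic")


def _make_config(config: MeanConfig | None, overrides: dict) -> MeanConfig:
    if config is None:
        return MeanConfig(**overrides)
    if overrides:
        fields = {**config.__dict__, **overrides}
        return MeanConfig(**fields)
    return config
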