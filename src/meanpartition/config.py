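"""Shared search configuration and helpers for the mean-partition engines.

Both engines (classic and dynamic) consume the same :class:`MeanConfig` and
the same initial-candidate rule, and evaluate the same weighted objective
through :func:`weighted_objective`, so that — given identical configuration —
their accept/reject decisions and move traces are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .sample import PosteriorSample

__all__ = ["MeanConfig", "weighted_objective", "initial_candidate"]

_INITS = ("best-sample", "singletons", "one-cluster", "crp", "given")
_STRATEGIES = ("rematch", "case-analysis")


@dataclass
class MeanConfig:
    """Configuration of the local search.

    exponent
        Power applied to each distance in the objective
        ``sum_k w_k * D(candidate, P_k)^exponent``; 2 (squared distance, the
        default) or 1.
    init
        Initial candidate rule: ``best-sample`` (the sample partition with
        the lowest objective; cheap, deterministic, never worse than the
        best sample), ``singletons``, ``one-cluster``, ``crp`` (a random
        Chinese-restaurant draw, seeded) or ``given`` (start from
        ``initial``).
    best_of_row
        If False (default), the first strictly-improving target cluster for
        an element is accepted greedily; if True, all targets are evaluated
        and the best is taken.
    strategy
        Dynamic engine only: ``rematch`` applies the row update plus one
        Hungarian augmentation per candidate move; ``case-analysis``
        predicts each move's per-graph cost change from the current graph
        and only touches the graphs on acceptance.  Both must produce
        identical traces.
    max_cycles
        Safety cap on full element scans; hitting it flags the result as
        non-converged.
    """

    exponent: int = 2
    init: str = "best-sample"
    best_of_row: bool = False
    strategy: str = "rematch"
    max_cycles: int = 1000
    seed: int | None = None
    verify: bool = False
    initial: object = None  # Partition or label array, for init="given"

    def __post_init__(self):
        if self.exponent not in (1, 2):
            raise ConfigError("exponent must be 1 or 2")
        if self.init not in _INITS:
            raise ConfigError(f"init must be one of {_INITS}")
        if self.init == "given" and self.initial is None:
            raise ConfigError("init='given' requires an initial candidate")
        if self.strategy not in _STRATEGIES:
            raise ConfigError(f"strategy must be one of {_STRATEGIES}")
        if self.max_cycles < 1:
            raise ConfigError("max_cycles must be >= 1")


def weighted_objective(distances, weights, exponent: int = 2) -> float:
    """``sum_k w_k * d_k^exponent`` with a fixed accumulation order.

    All engines route their objective evaluations through this single
    helper so that equal integer distance vectors always produce the same
    float, making trace comparisons exact.
    """
    d = np.asarray(distances, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if exponent == 1:
        return float(w @ d)
    return float(w @ (d * d))


def initial_candidate(sample: PosteriorSample, config: MeanConfig) -> np.ndarray:
    """Initial candidate labels (compact ids 0..C-1) for the local search."""
    from .distance import partition_distance  # local import: keep modules light

    n = sample.n_elements
    if config.init == "given":
        from .partitions import canonicalize
        labels = canonicalize(config.initial).labels.copy()
        if labels.shape[0] != n:
            raise ConfigError("initial candidate has the wrong element count")
        return labels
    if config.init == "singletons":
        return np.arange(n, dtype=np.int64)
    if config.init == "one-cluster":
        return np.zeros(n, dtype=np.int64)
    if config.init == "crp":
        from .simgen import sample_crp
        return sample_crp(n, alpha=1.0, seed=config.seed).labels.copy()
    # best-sample: the sample partition with the lowest objective, ties by index
    k = sample.k
    dmat = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            dmat[i, j] = dmat[j, i] = partition_distance(
                sample.partitions[i], sample.partitions[j])
    objs = [weighted_objective(dmat[i], sample.weights, config.exponent)
            for i in range(k)]
    best = int(np.argmin(objs))
    return sample.partitions[best].labels.copy()
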