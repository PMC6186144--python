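"""Synthetic partition generators with known structure.

Three constructions cover the benchmark and recovery scenarios:

* :func:`make_rm_pair` — the RM construction: a base partition ``A(C, M)``
  of C clusters with M consecutive elements each, and a copy with ``x``
  distinct elements each moved to a different existing cluster, emulating
  the misclassification errors of a reconstruction algorithm.  The
  partition distance of the pair is at most ``x``.
* :func:`sample_crp` — a Chinese-Restaurant-Process draw with concentration
  ``alpha``: element ``t`` joins an existing cluster ``c`` with probability
  ``|c| / (t + alpha)`` and opens a new cluster with probability
  ``alpha / (t + alpha)``.  The expected cluster count is exactly
  ``sum_{t=0}^{N-1} alpha / (alpha + t)``, approximately ``alpha * log N``
  for large ``N`` — the typical cluster count of a Dirichlet-process
  posterior.
* :func:`make_posterior` — K independent noisy copies of a known base
  partition (RM-style perturbations, unit weights), a stand-in for an MCMC
  posterior sample concentrated around its mode; used for consensus
  recovery tests.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .partitions import Partition
from .sample import PosteriorSample

__all__ = ["RMConfig", "CRPConfig", "make_rm_pair", "sample_crp",
           "make_posterior", "crp_expected_clusters"]


@dataclass(frozen=True)
class RMConfig:
    """RM benchmark pair: C clusters of M elements, x elements moved."""

    n_clusters: int
    cluster_size: int
    moved: int
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ConfigError("RM construction needs at least 2 clusters")
        if self.cluster_size < 1:
            raise ConfigError("cluster_size must be >= 1")
        if not 0 <= self.moved <= self.n_clusters * self.cluster_size:
            raise ConfigError("moved must satisfy 0 <= x <= C*M")

    def make_pair(self) -> tuple[Partition, Partition]:
        return make_rm_pair(self.n_clusters, self.cluster_size, self.moved,
                            seed=self.seed)


@dataclass(frozen=True)
class CRPConfig:
    """Chinese-Restaurant-Process draw of N elements at concentration alpha."""

    n_elements: int
    alpha: float
    seed: int = 0

    def __post_init__(self):
        if self.n_elements < 1:
            raise ConfigError("n_elements must be >= 1")
        if not self.alpha > 0:
            raise ConfigError("alpha must be > 0")

    def sample(self) -> Partition:
        return sample_crp(self.n_elements, self.alpha, seed=self.seed)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _move_elements(labels: np.ndarray, n_moves: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Move ``n_moves`` distinct elements, each to a different existing cluster.

    Elements are sampled without replacement; each target is drawn uniformly
    from the other non-empty clusters at move time (no new clusters beyond
    the original ids; if every other cluster has been emptied by earlier
    moves, an emptied original cluster may be revived).
    """
    labels = labels.astype(np.int64).copy()
    n = labels.shape[0]
    if n_moves > n:
        raise ConfigError(f"cannot move {n_moves} of {n} elements")
    n_clusters = int(labels.max()) + 1
    if n_clusters < 2 and n_moves > 0:
        raise ConfigError("need at least 2 clusters to move elements between")
    counts = np.bincount(labels, minlength=n_clusters)
    chosen = rng.choice(n, size=n_moves, replace=False)
    for p in chosen:
        src = int(labels[p])
        targets = [c for c in range(n_clusters) if counts[c] > 0 and c != src]
        if not targets:
            targets = [c for c in range(n_clusters) if c != src]
        dst = targets[int(rng.integers(len(targets)))]
        labels[p] = dst
        counts[src] -= 1
        counts[dst] += 1
    return labels


def make_rm_pair(n_clusters: int, cluster_size: int, moved: int,
                 seed=0) -> tuple[Partition, Partition]:
    """Generate an RM benchmark pair ``(P1, P2)``.

    ``P1`` has ``n_clusters`` clusters of ``cluster_size`` consecutive
    elements; ``P2`` is a copy with ``moved`` distinct uniformly chosen
    elements each reassigned to a uniformly chosen different existing
    cluster.  ``partition_distance(P1, P2) <= moved`` always (moving the
    same elements back equalizes the partitions).
    """
    cfg = RMConfig(n_clusters, cluster_size, moved, 0)  # validates bounds
    rng = _rng(seed)
    base = np.repeat(np.arange(cfg.n_clusters, dtype=np.int64),
                     cfg.cluster_size)
    perturbed = _move_elements(base, cfg.moved, rng)
    return Partition(base, _canonical=True), Partition(perturbed)


def sample_crp(n_elements: int, alpha: float, seed=0) -> Partition:
    """Draw one partition of ``n_elements`` from a CRP with concentration alpha."""
    CRPConfig(n_elements, alpha, 0)  # validates
    rng = _rng(seed)
    labels = np.zeros(n_elements, dtype=np.int64)
    counts = [1]
    u = rng.random(n_elements)
    for t in range(1, n_elements):
        # existing cluster c with prob |c|/(t+alpha), new with alpha/(t+alpha)
        r = u[t] * (t + alpha)
        acc = 0.0
        chosen = len(counts)
        for c, sz in enumerate(counts):
            acc += sz
            if r < acc:
                chosen = c
                break
        if chosen == len(counts):
            counts.append(1)
        else:
            counts[chosen] += 1
        labels[t] = chosen
    return Partition(labels, _canonical=True)


def crp_expected_clusters(n_elements: int, alpha: float) -> float:
    """Exact expected cluster count ``sum_{t=0}^{N-1} alpha / (alpha + t)``."""
    t = np.arange(n_elements, dtype=float)
    return float(np.sum(alpha / (alpha + t)))


def make_posterior(base: Partition, k: int, noise_moves: int,
                   seed=0) -> PosteriorSample:
    """K independent noisy copies of ``base`` with unit weights.

    Each copy is perturbed by ``noise_moves`` random element moves (RM
    style).  With ``noise_moves=0`` the sample is K identical copies and
    the mean algorithms return ``base`` with objective 0.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if noise_moves < 0:
        raise ConfigError("noise_moves must be >= 0")
    rng = _rng(seed)
    parts = [Partition(_move_elements(base.labels, noise_moves, rng))
             for _ in range(k)]
    return PosteriorSample(parts, np.ones(k))
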