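"""Containers for weighted partition samples and mean-partition results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import ConfigError, EmptySampleError, IncompatiblePartitionsError
from .partitions import Partition, _collapse, canonicalize

__all__ = ["PosteriorSample", "MeanResult", "MoveRecord"]


class MoveRecord(NamedTuple):
    """One accepted local-search move.

    ``source``/``target`` are working cluster ids of the candidate at move
    time (``target == C`` denotes a freshly created cluster); ``objective``
    is the weighted objective immediately after the move.
    """

    element: int
    source: int
    target: int
    objective: float


@dataclass
class PosteriorSample:
    """K partitions over the same element set with positive weights.

    Weights default to 1 per partition; with duplicate collapsing they are
    the multiplicities, i.e. the empirical posterior probabilities up to a
    constant factor.
    """

    partitions: list[Partition]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.partitions = [canonicalize(p) for p in self.partitions]
        if len(self.partitions) == 0:
            raise EmptySampleError("a posterior sample needs at least one partition")
        n = self.partitions[0].n_elements
        for p in self.partitions:
            if p.n_elements != n:
                raise IncompatiblePartitionsError(
                    "all sample partitions must share the same element set")
        if self.weights is None:
            self.weights = np.ones(len(self.partitions), dtype=float)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.partitions),):
                raise ConfigError("weights must have one entry per partition")
            if not np.all(self.weights > 0):
                raise ConfigError("weights must be strictly positive")

    @classmethod
    def from_labels(cls, X, weights=None, *, collapse: bool = False) -> "PosteriorSample":
        """Build a sample from a (K, N) integer label matrix."""
        X = np.asarray(X)
        if X.ndim != 2:
            raise ConfigError("expected a 2-D (K, N) label matrix")
        parts = [Partition(row) for row in X]
        w = (np.ones(len(parts)) if weights is None
             else np.asarray(weights, dtype=float))
        if collapse:
            parts, w = _collapse(parts, w)
        return cls(parts, w)

    def collapsed(self) -> "PosteriorSample":
        parts, w = _collapse(self.partitions, self.weights)
        return PosteriorSample(parts, w)

    @property
    def k(self) -> int:
        return len(self.partitions)

    @property
    def n_elements(self) -> int:
        return self.partitions[0].n_elements

    def __len__(self) -> int:
        return self.k

    def __iter__(self):
        return iter(self.partitions)


@dataclass
class MeanResult:
    """Outcome of a mean-partition search.

    The returned ``mean`` is a local optimum: no single-element move
    (including to a new cluster) strictly improves the objective.
    """

    mean: Partition
    objective: float
    cycles: int
    moves: list[MoveRecord]
    converged: bool
    algorithm: str = ""
    strategy: str = ""

    @property
    def n_moves(self) -> int:
        return len(self.moves)
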