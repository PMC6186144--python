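"""Core partition data type, canonicalization, comparison helpers and I/O.

A :class:`Partition` is an exact set partition of the elements ``0..N-1``
into non-empty clusters.  Internally it is stored as an integer label vector
in *canonical form*: clusters are numbered by order of first appearance when
scanning elements ``0..N-1``.  Canonical numbering makes partitions directly
comparable and output files diffable.

Two plain-text formats are supported:

``lines``
    One partition per line; ``N`` whitespace- or comma-separated cluster
    labels, element order fixed across lines.  Labels may be arbitrary
    tokens; they are canonicalized on input.  Blank lines and lines starting
    with ``#`` are ignored.

``json``
    ``{"n": N, "partitions": [{"labels": [...], "weight": w}, ...]}`` with an
    optional positive weight per partition (default 1).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    EmptySampleError,
    IncompatiblePartitionsError,
    InvalidPartitionError,
    PartitionFormatError,
)

__all__ = [
    "Partition",
    "canonicalize",
    "effective_size",
    "read_partitions",
    "write_partitions",
]


def _canonical_labels(values: Iterable) -> np.ndarray:
    """Relabel arbitrary hashable cluster labels by order of first appearance."""
    values = list(values)
    if len(values) == 0:
        raise InvalidPartitionError("a partition needs at least one element")
    out = np.empty(len(values), dtype=np.int64)
    seen: dict = {}
    for idx, v in enumerate(values):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise InvalidPartitionError(f"element {idx} has no cluster assignment")
        out[idx] = seen.setdefault(v, len(seen))
    return out


class Partition:
    """An exact set partition of elements ``0..N-1`` in canonical form.

    Parameters
    ----------
    labels : sequence
        Per-element cluster labels (arbitrary hashables).  They are
        canonicalized: clusters are renumbered ``0..C-1`` by order of first
        appearance.

    Examples
    --------
    >>> Partition(["b", "b", "a"]).labels
    array([0, 0, 1])
    >>> Partition([5, 5, 5, 9]).labels
    array([0, 0, 0, 1])
    """

    __slots__ = ("_labels", "_clusters")

    def __init__(self, labels: Sequence, *, _canonical: bool = False):
        if _canonical:
            arr = np.asarray(labels, dtype=np.int64)
        else:
            arr = _canonical_labels(labels)
        arr.setflags(write=False)
        self._labels = arr
        self._clusters: tuple | None = None

    @classmethod
    def from_assignment(cls, assignment: Mapping[int, object],
                        n_elements: int | None = None) -> "Partition":
        """Build a partition from an element -> cluster-label mapping.

        Every element ``0..N-1`` must be present; a missing element raises
        :class:`InvalidPartitionError`.
        """
        n = len(assignment) if n_elements is None else n_elements
        try:
            values = [assignment[i] for i in range(n)]
        except KeyError as exc:
            raise InvalidPartitionError(
                f"element {exc.args[0]} has no cluster assignment") from None
        if n_elements is None and set(assignment) != set(range(n)):
            raise InvalidPartitionError("assignment keys must be exactly 0..N-1")
        return cls(values)

    # -- basic properties -------------------------------------------------

    @property
    def labels(self) -> np.ndarray:
        """Canonical per-element cluster indices (read-only array)."""
        return self._labels

    @property
    def n_elements(self) -> int:
        return int(self._labels.shape[0])

    @property
    def n_clusters(self) -> int:
        return int(self._labels.max()) + 1

    @property
    def clusters(self) -> tuple:
        """Clusters as a tuple of frozensets, indexed ``0..C-1``."""
        if self._clusters is None:
            groups: list[list[int]] = [[] for _ in range(self.n_clusters)]
            for el, c in enumerate(self._labels):
                groups[c].append(el)
            self._clusters = tuple(frozenset(g) for g in groups)
        return self._clusters

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self._labels, minlength=self.n_clusters)

    # -- dunder -----------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self._labels.shape == other._labels.shape and bool(
            np.array_equal(self._labels, other._labels))

    def __hash__(self) -> int:
        return hash(self._labels.tobytes())

    def __len__(self) -> int:
        return self.n_elements

    def __repr__(self) -> str:
        body = " ".join(map(str, self._labels[:20]))
        tail = " ..." if self.n_elements > 20 else ""
        return f"Partition(N={self.n_elements}, C={self.n_clusters}, [{body}{tail}])"


def canonicalize(p) -> Partition:
    """Return the canonical relabeling of ``p``.

    ``p`` may be a :class:`Partition` (returned as-is; construction already
    canonicalizes, so this is idempotent), a label sequence, or an
    element -> label mapping.
    """
    if isinstance(p, Partition):
        return p
    if isinstance(p, Mapping):
        return Partition.from_assignment(p)
    return Partition(p)


def _require_same_n(p1: Partition, p2: Partition) -> None:
    if p1.n_elements != p2.n_elements:
        raise IncompatiblePartitionsError(
            f"partitions have different element counts: "
            f"{p1.n_elements} != {p2.n_elements}")


def effective_size(p1: Partition, p2: Partition) -> int:
    """Effective partition size of a pair.

    Removes every cluster whose element set occurs identically in both
    partitions and returns the maximum of the remaining cluster counts.
    This is the quantity that governs the practical cost of a partition
    distance computation: identical clusters can always be matched at zero
    cost and contribute nothing.
    """
    p1, p2 = canonicalize(p1), canonicalize(p2)
    _require_same_n(p1, p2)
    shared = set(p1.clusters) & set(p2.clusters)
    r1 = sum(1 for c in p1.clusters if c not in shared)
    r2 = sum(1 for c in p2.clusters if c not in shared)
    return max(r1, r2)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _collapse(partitions: list[Partition],
              weights: np.ndarray) -> tuple[list[Partition], np.ndarray]:
    """Merge duplicate partitions, summing weights, keeping first-seen order."""
    index: dict[Partition, int] = {}
    out_p: list[Partition] = []
    out_w: list[float] = []
    for p, w in zip(partitions, weights):
        if p in index:
            out_w[index[p]] += float(w)
        else:
            index[p] = len(out_p)
            out_p.append(p)
            out_w.append(float(w))
    return out_p, np.asarray(out_w, dtype=float)


def read_partitions(source, format: str = "lines", *,
                    collapse: bool = False) -> tuple[list[Partition], np.ndarray]:
    """Read partitions (and weights) from a path or file-like object.

    Returns ``(partitions, weights)``; weights default to 1 per partition.
    With ``collapse=True`` duplicate partitions are merged into one record
    whose weight is the sum (the multiplicity for unit weights).
    """
    close = False
    if isinstance(source, (str, Path)):
        stream: IO = open(source, "r")
        close = True
    else:
        stream = source
    try:
        if format == "lines":
            partitions: list[Partition] = []
            for lineno, line in enumerate(stream, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tokens = line.replace(",", " ").split()
                p = Partition(tokens)
                if partitions and p.n_elements != partitions[0].n_elements:
                    raise PartitionFormatError(
                        f"line {lineno}: expected {partitions[0].n_elements} "
                        f"labels, got {p.n_elements}")
                partitions.append(p)
            weights = np.ones(len(partitions), dtype=float)
        elif format == "json":
            doc = json.load(stream)
            try:
                n = int(doc["n"])
                records = doc["partitions"]
            except (KeyError, TypeError) as exc:
                raise PartitionFormatError(f"bad JSON schema: {exc}") from None
            partitions, wlist = [], []
            for rec in records:
                p = Partition(rec["labels"])
                if p.n_elements != n:
                    raise PartitionFormatError(
                        f"partition has {p.n_elements} labels, header says {n}")
                partitions.append(p)
                wlist.append(float(rec.get("weight", 1.0)))
            weights = np.asarray(wlist, dtype=float)
        else:
            raise ValueError(f"unknown format {format!r}")
    finally:
        if close:
            stream.close()

    if not partitions:
        raise EmptySampleError("input contains no partitions")
    if collapse:
        partitions, weights = _collapse(partitions, weights)
    return partitions, weights


def write_partitions(partitions: Sequence[Partition], dest,
                     format: str = "lines", *,
                     weights: Sequence[float] | None = None,
                     collapse: bool = False) -> None:
    """Write partitions to a path or file-like object.

    The ``json`` format carries weights; ``lines`` does not (writing
    non-uniform weights in ``lines`` format raises).  ``read(write(ps))``
    reproduces canonical forms (and, for JSON, weights) bit-exactly.
    """
    partitions = [canonicalize(p) for p in partitions]
    if not partitions:
        raise EmptySampleError("nothing to write")
    n = partitions[0].n_elements
    for p in partitions:
        if p.n_elements != n:
            raise IncompatiblePartitionsError("partitions have heterogeneous N")
    if weights is None:
        w = np.ones(len(partitions), dtype=float)
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape[0] != len(partitions):
            raise ValueError("weights length does not match partitions")
    if collapse:
        partitions, w = _collapse(list(partitions), w)

    close = False
    if isinstance(dest, (str, Path)):
        stream: IO = open(dest, "w")
        close = True
    else:
        stream = dest
    try:
        if format == "lines":
            if not np.all(w == w[0]):
                raise ValueError("'lines' format cannot carry weights; use 'json'")
            for p in partitions:
                stream.write(" ".join(map(str, p.labels)) + "\n")
        elif format == "json":
            doc = {"n": n, "partitions": [
                {"labels": [int(v) for v in p.labels], "weight": float(wk)}
                for p, wk in zip(partitions, w)]}
            json.dump(doc, stream, indent=1)
            stream.write("\n")
        else:
            raise ValueError(f"unknown format {format!r}")
    finally:
        if close:
            stream.close()
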