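"""Exception hierarchy for :mod:`meanpartition`.

All package-specific errors derive from :class:`MeanPartitionError` so callers
can catch the whole family with a single ``except`` clause.
"""


class MeanPartitionError(Exception):
    """Base class for all errors raised by this package."""


class InvalidPartitionError(MeanPartitionError, ValueError):
    """An assignment does not describe a valid partition of 0..N-1."""


class IncompatiblePartitionsError(MeanPartitionError, ValueError):
    """Two partitions (or a partition and a sample) do not share an element set."""


class PartitionFormatError(MeanPartitionError, ValueError):
    """A partition file or stream is malformed (e.g. ragged line lengths)."""


class EmptySampleError(MeanPartitionError, ValueError):
    """An operation that needs at least one partition received none."""


class NothingToAugmentError(MeanPartitionError, RuntimeError):
    """An augmentation step was requested on a graph with no unmatched worker."""


class InconsistentStateError(MeanPartitionError, RuntimeError):
    """A dynamic graph state and the requested operation disagree.

    Raised e.g. when restoring a stale snapshot or when the element being
    moved is not in the cluster the caller claims it is in.
    """


class ConfigError(MeanPartitionError, ValueError):
    """A configuration value is out of range or internally contradictory."""
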