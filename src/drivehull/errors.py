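"""Exception hierarchy for the pipeline."""


class DriveHullError(Exception):
    """Base class for all pipeline errors."""


class AccelIOError(DriveHullError):
    """Fatal file I/O problem (missing input, unwritable output)."""


class EmptySeriesError(DriveHullError):
    """Fewer than two valid samples after parsing."""


class CorruptTimelineError(DriveHullError):
    """Timestamps not strictly increasing even after sorting (duplicates)."""


class DisjointRecordingsError(DriveHullError):
    """Wrist and vehicle recordings share no overlapping time coverage."""


class SeriesTooShortError(DriveHullError):
    """Series shorter than the envelope smoothing window."""


class SegmentMismatchError(DriveHullError):
    """A drive segment lies outside the time range of the series."""


class NoPointsError(DriveHullError):
    """Hull requested on an empty point cloud."""


class NoDrivesError(DriveHullError):
    """Participant-level aggregation requested with no drives."""


class InsufficientCohortError(DriveHullError):
    """Cohort statistics need at least four values."""


class NonPositiveVolumeError(DriveHullError):
    """log10 comparison requires strictly positive volumes."""
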