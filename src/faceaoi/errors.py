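"""Exception hierarchy for the pipeline.

Every named error condition raised by the library derives from
:class:`FaceAOIError`, so callers (and the CLI) can catch one type.
"""


class FaceAOIError(Exception):
    """Base class for all faceaoi errors."""


class MalformedHeaderError(FaceAOIError):
    """A CSV file lacks required columns or carries unexpected ones."""


class EmptyFileError(FaceAOIError):
    """A data file contains a header but no rows (or nothing at all)."""


class NonMonotonicTimestampsError(FaceAOIError):
    """Timestamps are not strictly increasing."""


class DomainError(FaceAOIError):
    """An argument lies outside the mathematical domain of an operation."""


class InvalidFrameError(FaceAOIError):
    """A landmark frame with success=False was passed where a valid one is required."""


class AllFramesInvalidError(FaceAOIError):
    """Every frame of a landmark track failed detection."""


class InvalidCentersError(FaceAOIError):
    """AOI centers are missing/invalid where valid centers are required."""


class EmptyStreamError(FaceAOIError):
    """A label or paired-gaze stream has no samples."""


class UnknownLabelError(FaceAOIError):
    """A combine map references a label that does not exist."""


class LengthMismatchError(FaceAOIError):
    """Two tracks being compared have different lengths."""


class NoOverlappingValidFramesError(FaceAOIError):
    """Two tracks share no frame where both are valid."""


class InsufficientDataError(FaceAOIError):
    """Fewer than two consecutive valid frames: temporal stats undefined."""


class WindowTooLargeError(FaceAOIError):
    """A rolling window exceeds the track length."""


class AllFramesFlaggedError(FaceAOIError):
    """Spike filtering is impossible: every frame is flagged."""


class InvalidConfigError(FaceAOIError):
    """A simulation or run configuration violates its invariants."""


class ScheduleOverflowError(FaceAOIError):
    """A gaze dwell schedule is longer than the available center track."""


class ScheduleMismatchError(FaceAOIError):
    """Dyad schedules/configs are inconsistent in duration."""
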