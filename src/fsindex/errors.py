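"""Exception hierarchy shared across the package.

Every error raised by fsindex derives from :class:`FsindexError`, so callers
(and the CLI) can catch one type. Stage-level failures in the pipeline are
wrapped in :class:`StageError` which carries the name of the failing stage.
"""

from __future__ import annotations


class FsindexError(Exception):
    """Base class for all fsindex errors."""


class InvalidLimitError(FsindexError):
    """Raised when a (min, max) permissible-limit pair is inconsistent."""


class InvalidMeasurementError(FsindexError):
    """Raised for a negative or non-finite test result."""


class MissingLimitError(FsindexError):
    """Raised when a record lacks the limit required to score it."""


class MissingWeightError(FsindexError):
    """Raised when a required weight (hazard, channel, consumption) is absent."""


class InvalidParameterError(FsindexError):
    """Raised for out-of-range configuration parameters."""


class DegenerateInputError(FsindexError):
    """Raised when an input is structurally unusable (all-zero, constant...)."""


class InsufficientDataError(FsindexError):
    """Raised when there are too few observations for the operation."""


class AlignmentError(FsindexError):
    """Raised when two paired series cannot be aligned."""


class RetentionError(FsindexError):
    """Raised when factor retention leaves no factors."""


class ConfigError(FsindexError):
    """Raised for invalid run or campaign configuration."""


class EmptyReportError(FsindexError):
    """Raised when aggregation receives no scored samples."""


class StageError(FsindexError):
    """Pipeline failure tagged with the stage that produced it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
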