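"""Exception hierarchy for gaitage.

Every error raised by the library derives from :class:`GaitageError` so
callers can catch the whole family with one clause.
"""


class GaitageError(Exception):
    """Base class for all gaitage errors."""


class FormatError(GaitageError):
    """A file does not conform to the expected on-disk schema."""


class SamplingError(GaitageError):
    """Timestamps are not uniformly spaced at the declared rate."""


class SchemaError(GaitageError):
    """A feature table or manifest violates the declared column census."""


class IntegrityError(GaitageError):
    """Duplicate or inconsistent identifiers within a cohort."""


class ParameterError(GaitageError):
    """A parameter value is outside its valid domain."""


class SegmentationError(GaitageError):
    """Event detection found an unexpected number or ordering of events."""


class TrainingError(GaitageError):
    """The regression model could not be trained or is not yet trained."""


class ExtractionError(GaitageError):
    """A feature could not be computed from an otherwise valid recording."""


class RegularityError(ExtractionError):
    """No autocorrelation peak was found in the configured lag window."""
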