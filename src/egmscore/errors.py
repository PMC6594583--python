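"""Exception hierarchy for electrogram analysis.

Every error raised by this package derives from :class:`EgmError`, so callers
(and the CLI) can distinguish analysis failures from programming errors.
"""


class EgmError(Exception):
    """Base class for all egmscore errors."""


class FormatError(EgmError):
    """A file does not conform to the expected text dialect or schema layout."""


class ChannelMissingError(FormatError):
    """A required channel column is absent from a signal export."""


class SamplingError(EgmError):
    """The time axis is non-uniform or inconsistent with the declared rate."""


class SchemaError(EgmError):
    """A feature table lacks required columns or has an unusable outcome column."""


class ValidationError(EgmError):
    """Input data violate an invariant (duplicate ids, missing scores, ...)."""


class ParameterError(EgmError):
    """A configuration or function parameter is out of its valid range."""


class InsufficientDataError(EgmError):
    """A trace is too short for the requested filtering operation."""


class DetectionError(EgmError):
    """A landmark could not be detected (flat trace, no threshold crossing)."""


class NoBeatError(DetectionError):
    """No complete cardiac cycle precedes the energy-onset time."""


class ComputationError(EgmError):
    """A derived quantity cannot be computed (e.g. window outside the beat)."""


class EgmWarning(UserWarning):
    """Non-fatal analysis condition (e.g. noise baseline overlaps activity)."""
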