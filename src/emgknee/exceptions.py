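"""Exception hierarchy shared across the package."""


class EmgKneeError(Exception):
    """Base class for all package errors."""


class FormatError(EmgKneeError):
    """A recording on disk violates the on-disk dialect or its invariants."""


class ParameterError(EmgKneeError):
    """An operation was called with parameters outside its valid range."""


class EmptyInputError(EmgKneeError):
    """Input too short/empty for the requested operation."""


class AlignmentError(EmgKneeError):
    """A window end time falls outside the angle stream's time span."""


class DegenerateScaleError(EmgKneeError):
    """Target scaling requested on constant targets."""


class WindowSizeError(EmgKneeError):
    """A window is too short for the requested feature computation."""


class DimensionError(EmgKneeError):
    """Array shapes are inconsistent with the operation's contract."""


class NumericError(EmgKneeError):
    """Non-finite values encountered where finite values are required."""


class PartitionError(EmgKneeError):
    """A cross-validation partition cannot be formed as requested."""


class MetricError(EmgKneeError):
    """A metric is undefined for the given inputs (e.g. constant series)."""


class StateError(EmgKneeError):
    """A model object was used before it was fitted/initialized."""


class ConfigError(EmgKneeError):
    """An experiment configuration field is invalid."""
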