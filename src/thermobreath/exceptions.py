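"""Exception hierarchy shared across the pipeline."""


class ThermoBreathError(Exception):
    """Base class for all package errors."""


class ValidationError(ThermoBreathError):
    """Data violates a container invariant (range, shape, binaryness)."""


class FormatError(ThermoBreathError):
    """A file is missing required structure or metadata."""


class InvalidParameterError(ThermoBreathError, ValueError):
    """A caller-supplied parameter is outside its domain."""


class DegenerateInputError(ThermoBreathError):
    """Input carries no usable contrast or variation (e.g. constant frame)."""


class GenerationError(ThermoBreathError):
    """Synthetic scene could not be rendered under the given geometry."""


class AlignmentError(ThermoBreathError):
    """Paired sequences disagree in frame count or frame shape."""


class EmptyRoiError(ThermoBreathError):
    """An aggregation was requested on an empty region of interest."""


class UndefinedMetricError(ThermoBreathError):
    """A metric is undefined for the given inputs (e.g. recall with no GT)."""


class EstimationError(ThermoBreathError):
    """Rate estimation failed (no detectable breathing signal)."""
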