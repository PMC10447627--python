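"""Named exception types raised across the pipeline."""


class SonokinError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(SonokinError, ValueError):
    """An array has the wrong length or dimensionality for the stage."""


class NonFiniteError(SonokinError, ValueError):
    """Input contains NaN or infinite values where finite data is required."""


class ConfigurationError(SonokinError, ValueError):
    """A parameter value is inconsistent with the pipeline geometry or options."""


class DepthRangeError(SonokinError, ValueError):
    """A modulated reflector depth leaves the transducer's penetration span."""


class SequencingError(SonokinError, ValueError):
    """Stream ticks arrived out of order or with gaps."""


class InsufficientDataError(SonokinError, ValueError):
    """Too few rows/events to fit a model or compute a statistic."""


class EvaluationError(SonokinError, ValueError):
    """A metric is undefined for the given signals (e.g. constant reference)."""


class ParseError(SonokinError, ValueError):
    """A serialized trial or config file is malformed."""
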