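"""Exception hierarchy for the measurement pipeline."""


class CanopyThermError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CanopyThermError, ValueError):
    """Invalid configuration values (sizes, fractions, periods)."""


class ShapeError(CanopyThermError, ValueError):
    """Array dimensions do not match what an operation requires."""


class FormatError(CanopyThermError, ValueError):
    """On-disk data is malformed, non-physical, or in an unknown encoding."""


class ModelError(CanopyThermError, ValueError):
    """A model artifact is missing or incompatible."""


class FitError(CanopyThermError, ValueError):
    """Registration fit is degenerate (collinear or single-axis pairs)."""


class EmptyROIError(CanopyThermError, ValueError):
    """No temperature values to aggregate."""


class InsufficientROIError(CanopyThermError, ValueError):
    """Mask covers fewer thermal cells than the configured minimum."""


class ProtocolError(CanopyThermError, ValueError):
    """Repetition-selection strategy incompatible with the protocol."""


class StatisticsError(CanopyThermError, ValueError):
    """Not enough paired data for the requested statistic."""


class UndefinedFitError(CanopyThermError, ValueError):
    """Regression or correlation undefined (constant predictor)."""
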