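"""Exception hierarchy shared by all pipeline stages."""


class CardiotoxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CardiotoxError):
    """Invalid generator or pipeline configuration.

    Deliberately not a ValueError subclass: pydantic would swallow it into a
    ValidationError inside model validators, and callers are expected to
    handle it distinctly from malformed-input errors.
    """


class InputError(CardiotoxError, ValueError):
    """A function received data violating its preconditions."""


class InsufficientDataError(InputError):
    """Not enough data to compute the requested quantity (e.g. <1 cardiac cycle)."""


class SamplingError(InputError):
    """Sampling rate too low to resolve the cardiac cycle (<4 frames/cycle)."""


class CalibrationError(InputError):
    """Phantom calibration failed (depth mismatch beyond tolerance)."""


class DivisionError(CalibrationError):
    """Non-positive phantom reference level; the backscatter ratio is undefined."""


class DegenerateDesignError(InputError):
    """Regression design has no dose variation; the slope is undefined."""


class UndefinedCorrelationError(InputError):
    """A ranked vector has zero variance; rank correlation is undefined."""
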