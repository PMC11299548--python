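"""Exception and warning hierarchy.

Errors are deliberately loud: calibration work must not hide sensor
faults behind silent clipping or interpolation, so every out-of-range
input, degenerate design or unresolved column raises instead of
saturating.
"""


class StemWCError(Exception):
    """Base class for all package errors."""


class DomainError(StemWCError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class RangeError(DomainError):
    """Raw sensor counts outside a transform's declared valid range."""


class TransformDomainError(DomainError):
    """A permittivity transform produced a non-positive epsilon."""


class ConfigError(StemWCError, ValueError):
    """Invalid configuration (transform, registry or generator)."""


class CalibrationModeError(StemWCError):
    """Absolute application requested from a relative-only calibration."""


class DegenerateCalibrationError(StemWCError):
    """Calibration with zero slope cannot be inverted."""


class RankError(StemWCError, ValueError):
    """Design matrix is rank deficient (e.g. zero predictor variance)."""


class SpanError(StemWCError, ValueError):
    """Predictor span too narrow (e.g. temperature range < 2 degC)."""


class OrderingError(StemWCError, ValueError):
    """Non-monotone or duplicated ordering (timestamps, order_index)."""


class NestingError(StemWCError, ValueError):
    """Models passed to a likelihood-ratio test are not nested."""


class ConvergenceError(StemWCError, RuntimeError):
    """Mixed-model optimizer failed; carries optimizer diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(StemWCError, ValueError):
    """Input table misses required columns or fails row validation."""


class MetricsError(StemWCError, ValueError):
    """Fit metrics undefined (zero total sum of squares)."""


class BaselineError(StemWCError, ValueError):
    """Empty or unresolvable baseline window for delta-StWC."""


class WindowError(StemWCError, ValueError):
    """Analysis window too short (e.g. < 2 days for diurnal cycles)."""


class LabellingError(StemWCError, ValueError):
    """A period specification leaves timestamps unlabelled."""


class NegativeVWCWarning(UserWarning):
    """Calibration extrapolated to a negative water content (diagnostic)."""


class DataQualityWarning(UserWarning):
    """Row-level validation failures, gaps or suspicious values."""
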