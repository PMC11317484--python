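"""Exception hierarchy for the aldiet package."""


class AldietError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AldietError):
    """Invalid generator or pipeline configuration."""


class CalibrationError(AldietError):
    """Baseline-rate calibration could not reach the target."""


class NoEventsError(AldietError):
    """Survival data contain no events; a Cox model cannot be fit."""


class RankError(AldietError):
    """Design matrix is rank deficient (constant or collinear columns)."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = columns if columns is not None else []


class InsufficientDataError(AldietError):
    """Too few observations or events for the requested computation."""


class CodingError(AldietError):
    """A raw dietary value does not map to any level in the coding ledger."""


class SchemaError(AldietError):
    """Input table is missing required columns or has invalid values."""
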