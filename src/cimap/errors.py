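"""Exception hierarchy shared across the package."""


class CIMapError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CIMapError):
    """Data columns and variable dictionary disagree."""


class ValidationError(CIMapError):
    """A value is not a declared level of its variable."""


class DomainError(CIMapError):
    """An input violates a numeric precondition (e.g. negative count)."""


class EmptyTableError(CIMapError):
    """A contingency table has no usable records."""


class DegenerateTableError(CIMapError):
    """A margin of the table is zero, so the requested statistic is undefined."""


class InfeasibleTargetError(CIMapError):
    """A calibration target exceeds the maximum attainable under the constraints."""

    def __init__(self, message, maximum=None):
        super().__init__(message)
        self.maximum = maximum


class CalibrationError(CIMapError):
    """A numeric calibration failed to converge to the requested tolerance."""
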