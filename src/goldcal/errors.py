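"""Exception hierarchy for goldcal."""


class GoldcalError(Exception):
    """Base class for all goldcal errors."""


class InvalidReflectionError(GoldcalError):
    """Raised for a Miller index that does not define a lattice plane."""


class ConfigurationError(GoldcalError):
    """Raised for unsupported materials or invalid configuration values."""


class NoPeakError(GoldcalError):
    """Raised when no significant Bragg peak is found in a search annulus."""


class IncompleteRingError(GoldcalError):
    """Raised when too few azimuthal wedges yield a usable ring peak."""


class FitError(GoldcalError):
    """Raised when a background or ellipse fit is degenerate."""


class CalibrationError(GoldcalError):
    """Raised when every micrograph in a calibration run was rejected."""

    def __init__(self, message: str, reasons: dict[str, str] | None = None):
        super().__init__(message)
        self.reasons = reasons or {}


class StarParseError(GoldcalError):
    """Raised when a STAR file lacks the required table or field."""
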