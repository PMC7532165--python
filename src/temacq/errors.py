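"""Exception hierarchy shared across the acquisition pipeline."""


class TemacqError(Exception):
    """Base class for all package errors."""


class StageBoundsError(TemacqError):
    """A stage move or render was requested outside the stage range."""


class BarcodeNotFoundError(TemacqError):
    """A requested section barcode is absent from the tape, or a barcode
    strip could not be decoded."""


class InvalidCorrectionError(TemacqError):
    """The correction set is unusable (non-positive brightfield-darkfield
    denominator or shape mismatch)."""


class CalibrationError(TemacqError):
    """Pixel-size / beam-rotation calibration failed to match a template."""


class BeamCenteringError(TemacqError):
    """Beam centering could not reduce the illumination offset."""


class AutofocusError(TemacqError):
    """Autofocus found no usable peak (flat score curve or boundary hit)."""

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or f"autofocus failed: {reason}")


class MontageFocusError(TemacqError):
    """All focus measurement points (centroid and satellites) were rejected."""


class CentroidError(TemacqError):
    """Aperture centroid finding failed to bracket an edge transition."""


class RoiParseError(TemacqError, ValueError):
    """An acquisition-range expression could not be parsed."""


class StateTransitionError(TemacqError):
    """An illegal montage-record QC state transition was attempted."""
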