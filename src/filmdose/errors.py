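"""Exception hierarchy and warnings for the film dosimetry pipeline."""


class FilmDoseError(Exception):
    """Base class for all filmdose errors."""


class ScanFormatError(FilmDoseError):
    """Scan file is not a 16-bit-per-channel RGB image."""


class ROIBoundsError(FilmDoseError):
    """Requested ROI extends beyond the scanned image (no silent clipping)."""


class PairingError(FilmDoseError):
    """Before/after scans disagree in film model, lot or resolution."""


class FitError(FilmDoseError):
    """Calibration fit failed to converge or the design is degenerate."""


class ModelRejectionError(FilmDoseError):
    """Fitted calibration violates monotonicity/positivity on its range."""


class SaturationError(FilmDoseError):
    """Response at or beyond the rational model's asymptote c/b."""


class CalibrationIOError(FilmDoseError):
    """Calibration file missing fields, inconsistent, or wrong schema."""


class BeamQualityError(FilmDoseError):
    """Beam quality outside the packaged conversion table, or MV on kV path."""


class AggregationError(FilmDoseError):
    """Repeat measurements with mixed labels/protocols cannot be pooled."""


class ProfileError(FilmDoseError):
    """Invalid profile construction (duplicate positions, too few points)."""


class RegistryError(FilmDoseError):
    """Unknown machine/site combination in a packaged registry."""


class ExtrapolationWarning(UserWarning):
    """Dose or response outside the calibrated range; result extrapolated."""
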