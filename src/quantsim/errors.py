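"""Exception hierarchy shared across the package.

Grouped so the CLI can map classes of failure onto distinct exit codes:
layout/format problems (bad files, bad shapes) vs calibration problems
(unphysical fits, insufficient data).
"""


class QuantSimError(Exception):
    """Base class for all package-specific errors."""


class LayoutError(QuantSimError):
    """Raised when image data does not match the expected geometric layout.

    Examples: a concatenated phase image whose row count is not divisible
    by three, mismatched frame shapes within a flat-field level, or a 3D
    stack with inconsistent page dimensions.
    """


class FormatError(QuantSimError):
    """Raised on unreadable or structurally invalid files (TIFF mode,
    calibration-file schema, missing fields)."""


class CalibrationError(QuantSimError):
    """Raised when a calibration fit fails or yields unphysical values
    (non-positive gain, modulation contrast outside (0, 1], sigma = 0)."""


class InsufficientLevelsError(CalibrationError):
    """Raised when a flat-field series has too few usable illumination
    levels for the photon-transfer fit (more than five are required)."""


class EmptySelectionError(CalibrationError):
    """Raised when the bead-pixel selection rule selects no pixels."""
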