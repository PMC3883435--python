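"""Exception hierarchy for the chipcode pipeline.

Every stage raises a subclass of :class:`ChipcodeError` so callers (and the
CLI) can distinguish validation failures from programming errors and map them
to distinct exit codes.
"""


class ChipcodeError(Exception):
    """Base class for all chipcode validation and analysis errors."""


class LayoutError(ChipcodeError):
    """Layout config violates the documented schema or an invariant."""


class PairingError(LayoutError):
    """Control/analyte pairing is inconsistent (missing or duplicated partner)."""


class BoundsError(ChipcodeError):
    """A well address lies outside the declared plate grid."""


class FormatError(ChipcodeError):
    """Unsupported image mode or bit depth."""


class GeometryError(ChipcodeError):
    """A well ROI does not fit inside the image."""


class AssemblyError(ChipcodeError):
    """Digit set does not cover the code's slots exactly once."""


class EmptyLibraryError(ChipcodeError):
    """Identification requested against an empty code library."""


class CompatibilityError(ChipcodeError):
    """Codes of different length or digit ordering cannot be compared."""


class InputError(ChipcodeError):
    """Empty or malformed tabular input."""


class DegenerateDesignError(ChipcodeError):
    """Calibration design has fewer than two distinct concentrations."""


class FlatCurveError(ChipcodeError):
    """Standard-curve slope is numerically zero; concentration not identifiable."""


class DataError(ChipcodeError):
    """Spectral table violates its invariants (e.g. duplicated wavelength)."""


class WindowError(ChipcodeError):
    """Analysis window does not overlap the wavelength grid."""


class ExtrapolationError(ChipcodeError):
    """Requested wavelength lies outside the spectrum's grid span."""


class RegridError(ChipcodeError):
    """Spectra to be averaged do not share an identical wavelength grid."""


class ScenarioError(ChipcodeError):
    """Synthetic scenario is physically impossible (e.g. color out of range)."""
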