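"""Exception hierarchy shared across the package."""


class TangmorphError(Exception):
    """Base class for all package errors."""


class FormatError(TangmorphError):
    """An input file or table does not match the documented layout."""


class DegenerateOutlineError(TangmorphError):
    """An outline is too small or geometrically degenerate to analyse."""


class AmbiguousOrientationError(TangmorphError):
    """Automatic tang-side detection could not pick an end; supply a hint."""


class ParameterError(TangmorphError):
    """An argument is outside its documented range."""


class NormalizationError(TangmorphError):
    """Coefficient sets with incompatible harmonic count or normalization state."""


class ShoulderDetectionError(TangmorphError):
    """The tang/blade boundary could not be located on the width profile."""
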