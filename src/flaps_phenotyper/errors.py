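"""Exception hierarchy for the FLAPS phenotyping pipeline.

All package-specific failures derive from :class:`FlapsError` so callers can
catch one base class at CLI boundaries while tests assert on the precise
subclass.
"""


class FlapsError(Exception):
    """Base class for all errors raised by this package."""


class RegistrationError(FlapsError):
    """Channel rasters of one field of view do not share a common shape."""


class ConfigurationError(FlapsError):
    """Invalid user-supplied configuration (channel map, fractions, seeds...)."""


class FormatError(FlapsError):
    """An external file violates the documented format contract."""


class PlacementError(FlapsError):
    """The simulator could not place all objects without overlap."""


class DegenerateBackgroundError(FlapsError):
    """Background estimate is zero / too few background pixels remain."""


class DegenerateObjectError(FlapsError):
    """An operation received an empty reference object mask."""


class DegenerateChromatogramError(FlapsError):
    """A chromatogram carries no integrable signal."""


class CalibrationError(FlapsError):
    """Molecular-weight calibration cannot be computed."""


class ControlInsufficiencyError(FlapsError):
    """Too few control events survive the forward-scatter threshold."""


class GatingError(FlapsError):
    """No sample events survive the forward-scatter threshold."""


class InputError(FlapsError):
    """Structurally invalid input to an analysis operation."""
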