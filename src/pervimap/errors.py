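"""Exception hierarchy for the pervimap pipeline."""


class PervimapError(Exception):
    """Base class for all pervimap errors."""


class InputError(PervimapError):
    """A required input (file, sample, column) is missing or unusable."""


class FormatError(PervimapError):
    """A file exists but is not a valid volume/table of the expected kind."""


class GeometryError(PervimapError):
    """Two grids/objects that must share world geometry do not."""


class ValidationError(PervimapError):
    """A domain invariant is violated (range, emptiness, schema)."""


class SpecError(PervimapError):
    """A phantom or run specification is internally inconsistent."""


class UndefinedRatioError(ValidationError):
    """A ratio measure is requested with a non-positive denominator."""
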