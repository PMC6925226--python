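"""Exception hierarchy for capsgeom.

Analysis-path errors are always explicit: an empty selection or a broken
ring partition raises rather than propagating silently empty results.
"""


class CapsGeomError(Exception):
    """Base class for all capsgeom errors."""


class ParseError(CapsGeomError):
    """A coordinate file could not be parsed."""


class EmptyStructureError(CapsGeomError):
    """A coordinate file contained no atoms."""


class EmptySelectionError(CapsGeomError):
    """A selection used on an analysis path matched nothing."""


class DialectError(CapsGeomError):
    """The requested output dialect cannot represent the model."""


class ParameterError(CapsGeomError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateGeometryError(CapsGeomError):
    """Geometry is degenerate (zero-length vector, collinear points, ...)."""


class HelixTooShortError(CapsGeomError):
    """A helix interval has fewer residues than the vector estimate needs."""


class IncompleteBackboneError(CapsGeomError):
    """Residues in a helix interval are missing N/CA/C backbone atoms."""


class MissingAtomError(CapsGeomError):
    """A named diagnostic atom required by an analysis is absent."""


class RingDetectionError(CapsGeomError):
    """Chain contact components are not all pentamers or hexamers."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components or []
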