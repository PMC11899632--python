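"""Exception hierarchy for the plate-design pipeline.

Every stage raises a subclass of :class:`PsiPlateError` so the CLI can name
the failing stage and exit nonzero without a traceback.
"""


class PsiPlateError(Exception):
    """Base class for all package errors."""


class StlParseError(PsiPlateError):
    """Malformed STL input; message names the byte or line offset."""


class InvalidPlanError(PsiPlateError):
    """Plan points violate the minimum-size / distinctness rules."""


class ParameterError(PsiPlateError):
    """A numeric parameter is outside its documented domain."""


class DegenerateCurveError(PsiPlateError):
    """A sweep-path tangent or guide direction is numerically undefined."""


class DegenerateGeometryError(PsiPlateError):
    """A rectangle or triangle has (near-)zero area where area is required."""


class HoleLayoutError(PsiPlateError):
    """Hole centers too close together or otherwise unplaceable."""


class HoleSpecError(PsiPlateError):
    """Inconsistent countersink parameters."""


class SkinningError(PsiPlateError):
    """Corner correspondence flipped between consecutive cross-sections."""


class BooleanError(PsiPlateError):
    """Mesh Boolean precondition or intersection-loop failure."""


class SingularSystemError(PsiPlateError):
    """The statics system is rank deficient; message reports a null direction."""
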