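"""Exception hierarchy shared across the pipeline stages."""


class MedSegMeshError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MedSegMeshError, ValueError):
    """A parameter violates its documented precondition."""


class ShapeMismatchError(MedSegMeshError, ValueError):
    """Two arrays that must share a grid do not."""


class OutOfRangeError(MedSegMeshError, ValueError):
    """A coordinate or fraction lies outside its admissible interval."""


class InsufficientSlicesError(MedSegMeshError, ValueError):
    """A stack operation needs more slices than the volume has."""


class DegenerateGeometryError(MedSegMeshError, ValueError):
    """Geometric input is degenerate (coplanar points, zero-volume element...)."""


class DuplicateVertexError(MedSegMeshError, ValueError):
    """A point to be inserted coincides with an existing mesh vertex."""


class RobustnessError(MedSegMeshError, RuntimeError):
    """A geometric predicate cascade could not be resolved at the working
    precision (non-star-shaped insertion cavity, unrecoverable constraint...)."""


class WatertightnessError(MedSegMeshError, RuntimeError):
    """Exterior flood fill leaked through the constraint surface."""


class FlipRejectedError(MedSegMeshError, RuntimeError):
    """A local mesh transformation would create an inverted element."""


class NumericalInstabilityError(MedSegMeshError, RuntimeError):
    """An iterative scheme produced non-finite values."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
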