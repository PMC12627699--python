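"""Named error types raised by the screening-layer pipeline.

Each validation failure the pipeline can detect has its own class so that
callers (and the CLI) can report precisely which contract was violated.
"""


class ChscreenError(Exception):
    """Base class for all package errors."""


class RegistryError(ChscreenError):
    """Base class for trigger-registry validation failures."""


class DuplicateShortcodeError(RegistryError):
    pass


class ClassPrefixMismatchError(RegistryError):
    """Shortcode prefix (L_/P_) disagrees with the declared class."""


class EmptyCriteriaError(RegistryError):
    pass


class InvalidCriteriaError(RegistryError):
    """Criteria outside the set {1..5}."""


class MissingBinarizeRuleError(RegistryError):
    """A raster trigger without a comparator/threshold rule (or vice versa)."""


class CapacityExceededError(RegistryError):
    """More triggers than the combination encoding supports (Usage-Notes limit)."""


class UnknownShortcodeError(RegistryError):
    pass


class GridError(ChscreenError):
    pass


class GridAlignmentError(GridError):
    """Two grids (or a layer and a grid) do not share the same template."""


class GeometryError(ChscreenError):
    pass


class UnrepairableGeometryError(GeometryError):
    def __init__(self, index: int, message: str = ""):
        self.index = index
        super().__init__(message or f"geometry at index {index} could not be repaired")


class MixedGeometryError(GeometryError):
    pass


class PointOutsideExtentError(GeometryError):
    pass


class MissingAttributeError(ChscreenError):
    """A filter predicate references an attribute absent from the records."""


class ThresholdError(ChscreenError):
    """Binarization threshold outside [0, 1]."""


class RatConsistencyError(ChscreenError):
    """A combination-grid value has no record in the raster attribute table."""


class ProductValueError(ChscreenError):
    """A product grid contains values outside its allowed set."""
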