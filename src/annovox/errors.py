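"""Exception hierarchy.

Every error raised by the library derives from :class:`AnnotationError`,
so callers (and the CLI) can catch one base class.  Subclasses are fine
grained because the editing and workflow layers distinguish recoverable
conditions (contention, empty fill) from schema corruption.
"""


class AnnotationError(Exception):
    """Base class for all annovox errors."""


class SchemaError(AnnotationError):
    """Project-level annotation schema violated (duplicate name, bad value)."""


class CapacityError(AnnotationError):
    """The 64-bit mask budget of a single export word is exhausted."""


class UnknownROIError(AnnotationError, LookupError):
    """Named ROI is not defined in the project."""


class UnknownFieldError(AnnotationError, LookupError):
    """Named text field is not defined in the project."""


class LockedROIError(AnnotationError):
    """Edit targeted an ROI whose lock flag is set."""


class WrongToolError(AnnotationError):
    """Area tool applied to a point ROI or vice versa."""


class ValidationError(AnnotationError):
    """Value rejected by a constraint (restricted text value, bad spec)."""


class PermissionDeniedError(AnnotationError):
    """Workflow rights do not allow the requested transition or edit."""


class ContentionError(AnnotationError):
    """Series already owned by another user."""


class ShapeMismatchError(AnnotationError):
    """Two grids that must be congruent have different shapes."""


class UnsupportedShapeError(AnnotationError):
    """Loaded volume is not a 3-D grid."""


class UnknownLabelError(AnnotationError):
    """Imported mask contains bits absent from the sidecar mapping."""


class VersionNotFoundError(AnnotationError, LookupError):
    """Rollback target version id does not exist."""


class EmptyRegionError(AnnotationError):
    """Operation requires a nonempty ROI region on the slice."""


class PointNotFoundError(AnnotationError, LookupError):
    """Point annotation to remove does not exist."""


class ModelImportError(AnnotationError):
    """Model metadata failed validation or weights are missing."""


class ArchitectureError(AnnotationError):
    """Model architecture does not meet a method's structural requirement."""


class UnsupportedLayerError(AnnotationError):
    """Requested layer has no spatial feature maps."""
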