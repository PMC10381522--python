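"""Exception hierarchy for the enamel-thickness pipeline.

Every stage failure derives from :class:`EnamelMapError` so callers (and the
CLI) can distinguish pipeline-domain failures from programming errors.
"""


class EnamelMapError(Exception):
    """Base class for all pipeline errors."""


class FormatError(EnamelMapError):
    """Unreadable or unsupported mesh file format."""


class EmptyMeshError(EnamelMapError):
    """A mesh with no vertices or no faces where content is required."""


class DegenerateInputError(EnamelMapError):
    """Geometrically degenerate input (zero area, collapsed shape, ...)."""


class RepairError(EnamelMapError):
    """Hole filling failed, e.g. on a non-manifold edge."""


class NoInternalSurfaceError(EnamelMapError):
    """Surface classification found only one sheet (no EDJ)."""


class AmbiguousTopologyError(EnamelMapError):
    """Surface classification found more than two stable sheets."""


class MultiLoopError(EnamelMapError):
    """More than one candidate cervical-edge loop after filtering."""


class DegenerateEdgeError(EnamelMapError):
    """Cervical-edge points are (near) collinear; plane fit is rank deficient."""


class InsufficientContourError(EnamelMapError):
    """A contour has too few points for the requested operation."""


class ContourFailureError(EnamelMapError):
    """Automatic occlusal-contour search failed; supply overrides."""


class ProjectionFailureError(EnamelMapError):
    """Too many contour points failed to project onto the EDJ surface."""


class SegmentationError(EnamelMapError):
    """Sector segmentation received inconsistent contours."""


class ReportError(EnamelMapError):
    """Measurement report could not be assembled."""


class DomainError(EnamelMapError):
    """A measured quantity violated its domain (non-positive area, ...)."""
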