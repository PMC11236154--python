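"""Exception hierarchy shared across the pipeline."""


class SpermShapeError(Exception):
    """Base class for all package errors."""


class ParameterError(SpermShapeError, ValueError):
    """An input parameter violates its documented constraint."""


class GeometryError(SpermShapeError, ValueError):
    """A contour or geometric object is degenerate or out of bounds."""


class SegmentationError(SpermShapeError, ValueError):
    """Image segmentation produced no usable foreground."""


class FormatError(SpermShapeError, ValueError):
    """A file or array does not match the expected layout."""


class MeasurementError(SpermShapeError, ValueError):
    """A per-cell measurement cannot be taken (e.g. empty mask)."""


class ValidationError(SpermShapeError, ValueError):
    """Cross-file consistency check failed (e.g. manifest mismatch)."""


class DegenerateVarianceError(SpermShapeError, ValueError):
    """A statistical model cannot be fit because the data have no variance."""
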