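"""Exception hierarchy for the gesturecap pipeline."""


class GestureCapError(Exception):
    """Base class for all gesturecap errors."""


class FormatError(GestureCapError):
    """Malformed input file or schema/stream mismatch."""


class GeometryError(GestureCapError):
    """Invalid camera geometry input."""


class BehindCameraError(GeometryError):
    """A 3D point has non-positive depth in the camera frame."""


class DegenerateGeometryError(GeometryError):
    """Triangulation geometry is degenerate (coincident centers, parallel rays)."""


class DegenerateFitError(GestureCapError):
    """Rigid fit requested on too few or rank-deficient correspondences."""


class AlignmentError(GestureCapError):
    """Temporal/spatial alignment inputs are inconsistent."""


class EmptySequenceError(AlignmentError):
    """Clap trimming and margin exclusion left no analysable frames."""


class ScaleEstimationError(AlignmentError):
    """No valid elbow-shoulder frame pair available for scale estimation."""


class PipelineError(GestureCapError):
    """Pipeline stage ordering or configuration problem."""
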