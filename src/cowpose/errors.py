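"""Exception hierarchy for the toolkit.

Every failure mode the public API signals is a subclass of
:class:`CowPoseError`, so callers (and the CLI, which maps them to exit
code 2) can catch one type.
"""


class CowPoseError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(CowPoseError, ValueError):
    """An argument violates a documented precondition."""


class InvalidRotationError(InvalidArgumentError):
    """Matrix is not a proper rotation (orthonormal, det +1)."""


class BehindCameraError(CowPoseError):
    """A 3D point has non-positive depth and cannot be projected."""


class InsufficientLandmarksError(CowPoseError):
    """Fewer visible 2D-3D correspondences than the solver needs."""


class DegenerateGeometryError(CowPoseError):
    """Visible model points are (near-)coplanar; pose is not recoverable."""


class NonConvergenceError(CowPoseError):
    """Iterative solver diverged (perspective corrections blew up)."""


class EmptySampleError(CowPoseError):
    """Synthetic sample generation dropped every landmark."""


class CannotRasterizeError(CowPoseError):
    """Too few visible landmarks to draw a raster."""


class UnsupportedShapeError(CowPoseError):
    """Annotation region shape outside the supported polygon/rect subset."""


class SchemaError(CowPoseError):
    """Tabular file is missing a required column."""


class UndefinedMetricError(CowPoseError):
    """Metric undefined for the given input (e.g. AP with zero truths)."""


class InsufficientDataError(CowPoseError):
    """Not enough training samples to fit the regressor."""
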