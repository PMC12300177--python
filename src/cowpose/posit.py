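"""POSIT: pose from orthography and scaling, with iterations.

Recovers a rigid rotation + translation from >= 4 non-coplanar 2D-3D
landmark correspondences and a single calibrated image (DeMenthon-style
classic POSIT).  Each iteration solves the scaled-orthographic pose
equations in closed form via the pseudoinverse of the (centered) model
point matrix, completes and orthonormalizes the two recovered rotation
rows, and then updates per-point perspective correction factors
eps_i = (R3 . (M_i - M_0)) / Tz from the current depth estimate.  On
noise-free perspective input the corrections converge to the true
perspective pose.

Occluded landmarks are simply excluded: the solver runs on the visible
subset, which must stay non-coplanar and of size >= 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InsufficientLandmarksError,
    NonConvergenceError,
)
from .geometry import CameraModel, PoseAngles, angles_from_rotation, project
from .schemes import LandmarkScheme

__all__ = ["CorrespondenceSet", "PoseSolution", "solve_posit", "estimate_pose"]

#: visible model points are "coplanar" when the smallest singular value of
#: the centered coordinate matrix falls below this fraction of the largest
COPLANARITY_RATIO = 1e-3

#: perspective corrections beyond this magnitude are treated as divergence
EPS_DIVERGENCE = 10.0


@dataclass(frozen=True)
class CorrespondenceSet:
    """Paired 3D model landmarks and 2D image observations.

    ``image_points`` is (n, 2) in pixels, aligned with ``scheme.labels``;
    ``visibility`` marks which landmarks were actually observed.
    """

    scheme: LandmarkScheme
    image_points: np.ndarray
    visibility: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.image_points, dtype=float)
        vis = np.asarray(self.visibility, dtype=bool)
        n = len(self.scheme)
        if pts.shape != (n, 2):
            raise InsufficientLandmarksError(
                f"image_points must be ({n}, 2), got {pts.shape}")
        if vis.shape != (n,):
            raise InsufficientLandmarksError(f"visibility must be ({n},)")
        object.__setattr__(self, "image_points", pts)
        object.__setattr__(self, "visibility", vis)

    @property
    def n_visible(self) -> int:
        return int(self.visibility.sum())

    def visible_subset(self) -> Tuple[np.ndarray, np.ndarray]:
        """(model_points, image_points) restricted to visible landmarks."""
        m = self.visibility
        return self.scheme.canonical_points[m], self.image_points[m]


@dataclass(frozen=True)
class PoseSolution:
    """Rotation + translation recovered by the solver.

    ``translation`` maps model to camera coordinates (X = R P + t), in
    model units; its z component is positive (object in front of the
    camera).  ``rmse_history`` holds the reprojection RMSE in pixels
    after each iteration.
    """

    rotation: np.ndarray
    translation: np.ndarray
    iterations: int
    converged: bool
    reprojection_rmse: float
    rmse_history: Tuple[float, ...] = field(default=(), repr=False)

    @property
    def angles(self) -> PoseAngles:
        return angles_from_rotation(self.rotation)


def _nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Project a 3x3 matrix onto the nearest proper rotation (polar, det +1)."""
    U, _, Vt = np.linalg.svd(M)
    D = np.diag([1.0, 1.0, float(np.sign(np.linalg.det(U @ Vt)))])
    return U @ D @ Vt


def solve_posit(
    corr: CorrespondenceSet,
    cam: CameraModel,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> PoseSolution:
    """Run classic POSIT on the visible correspondences.

    Parameters
    ----------
    corr : CorrespondenceSet
        At least 4 visible, non-coplanar landmarks.
    cam : CameraModel
        Pinhole intrinsics (focal length, principal point) in pixels.
    tol : float
        Convergence threshold on the largest change of any perspective
        correction factor eps_i between iterations.
    max_iter : int
        Iteration cap; ``converged`` reports whether ``tol`` was reached.
    """
    if corr.n_visible < 4:
        raise InsufficientLandmarksError(
            f"need >= 4 visible landmarks, have {corr.n_visible}")
    model, image = corr.visible_subset()

    centered = model - model.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] / sv[0] < COPLANARITY_RATIO:
        raise DegenerateGeometryError(
            "visible model points are near-coplanar; classic POSIT requires "
            "a non-coplanar constellation")

    f = cam.focal_length
    pp = np.asarray(cam.principal_point, dtype=float)
    # image coordinates relative to the principal point
    xy = image - pp
    M0 = model[0]
    A = model[1:] - M0                      # (n-1, 3)
    B = np.linalg.pinv(A)                   # (3, n-1)

    eps = np.zeros(len(model) - 1)
    R = np.eye(3)
    Tz = f  # placeholder; overwritten on first iteration
    rmse_history = []
    converged = False
    iterations = 0

    for iterations in range(1, max_iter + 1):
        xp = xy[1:, 0] * (1.0 + eps) - xy[0, 0]
        yp = xy[1:, 1] * (1.0 + eps) - xy[0, 1]
        I = B @ xp
        J = B @ yp
        s1 = np.linalg.norm(I)
        s2 = np.linalg.norm(J)
        if s1 <= 0 or s2 <= 0:
            raise DegenerateGeometryError("degenerate image configuration")
        R = _nearest_rotation(np.vstack([I / s1, J / s2,
                                         np.cross(I / s1, J / s2)]))
        s = 0.5 * (s1 + s2)
        Tz = f / s
        new_eps = (A @ R[2]) / Tz
        if np.max(np.abs(new_eps)) > EPS_DIVERGENCE:
            raise NonConvergenceError(
                "perspective corrections diverged (|eps| > "
                f"{EPS_DIVERGENCE:g})")
        delta = np.max(np.abs(new_eps - eps))
        eps = new_eps

        T0 = np.array([xy[0, 0] / s, xy[0, 1] / s, Tz])
        t = T0 - R @ M0
        proj = project(model, R, t, cam)
        rmse_history.append(float(np.sqrt(np.mean((proj - image) ** 2))))

        if delta < tol:
            converged = True
            break

    T0 = np.array([xy[0, 0] * Tz / f, xy[0, 1] * Tz / f, Tz])
    t = T0 - R @ M0
    return PoseSolution(
        rotation=R,
        translation=t,
        iterations=iterations,
        converged=converged,
        reprojection_rmse=rmse_history[-1],
        rmse_history=tuple(rmse_history),
    )


def estimate_pose(corr: CorrespondenceSet, cam: CameraModel, **kwargs) -> PoseAngles:
    """Yaw/pitch/roll (degrees) of the POSIT solution for ``corr``."""
    return solve_posit(corr, cam, **kwargs).angles
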