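"""Rotations, Euler angles and pinhole projection.

Orientation is described by three angles in degrees: yaw (rotation about
the vertical axis, turning left/right), pitch (about the side-to-side
axis, nodding up/down) and roll (about the front-to-back axis, tilting
side to side).  The camera/image frame is the usual computer-vision one:
x to the right, y down, z forward into the scene, right-handed.  Under
this convention the vertical axis is y, the side-to-side axis is x and
the front-to-back axis is z.

The Euler composition order is fixed package-wide as

    R = R_y(yaw) @ R_x(pitch) @ R_z(roll)

i.e. intrinsic yaw-then-pitch-then-roll, the common head-pose convention.
Canonical angle ranges are yaw, roll in [-180, 180) and pitch in
[-90, 90]; at pitch = +/-90 (gimbal lock) roll is defined to be 0 and yaw
absorbs the free angle.

All public interfaces use degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import BehindCameraError, InvalidArgumentError, InvalidRotationError

__all__ = [
    "PoseAngles",
    "CameraModel",
    "check_rotation",
    "rotation_from_angles",
    "angles_from_rotation",
    "project",
    "wrap_degrees",
]

#: tolerance for the orthonormality / determinant checks on rotation matrices
ROTATION_ATOL = 1e-9


def wrap_degrees(a):
    """Wrap angle(s) in degrees to the half-open interval [-180, 180)."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class PoseAngles:
    """A 3D orientation as yaw/pitch/roll in degrees.

    Canonical form has yaw, roll in [-180, 180) and pitch in [-90, 90];
    construction does not canonicalize (use :meth:`canonical`).
    """

    yaw: float
    pitch: float
    roll: float

    def as_array(self) -> np.ndarray:
        return np.array([self.yaw, self.pitch, self.roll], dtype=float)

    def canonical(self) -> "PoseAngles":
        """Equivalent angles in canonical ranges (gimbal: roll forced to 0)."""
        return angles_from_rotation(rotation_from_angles(self))

    def is_canonical(self, atol: float = 1e-12) -> bool:
        c = self.canonical()
        return bool(np.allclose(self.as_array(), c.as_array(), atol=atol))


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera intrinsics in pixel units (no distortion).

    Parameters
    ----------
    focal_length : float
        Focal length in pixels, > 0.
    principal_point : (float, float)
        Optical-axis pixel (px, py).
    image_size : (int, int)
        (width, height) in pixels, both > 0.
    """

    focal_length: float
    principal_point: tuple
    image_size: tuple

    def __post_init__(self):
        if not (np.isfinite(self.focal_length) and self.focal_length > 0):
            raise InvalidArgumentError("focal_length must be finite and > 0")
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise InvalidArgumentError("image_size components must be > 0")

    @classmethod
    def default(cls, image_size=(640, 480)) -> "CameraModel":
        """Stand-in intrinsics: focal = image width, principal point = center."""
        w, h = image_size
        return cls(focal_length=float(w), principal_point=(w / 2.0, h / 2.0),
                   image_size=(int(w), int(h)))


def check_rotation(R: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Validate that ``R`` is a proper rotation; returns it as float array.

    Raises :class:`InvalidRotationError` if R is not 3x3 orthonormal with
    determinant +1 within ``atol``.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        raise InvalidRotationError("rotation must be a finite 3x3 matrix")
    if np.max(np.abs(R.T @ R - np.eye(3))) > atol:
        raise InvalidRotationError("matrix is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > atol:
        raise InvalidRotationError("matrix is not proper (det != +1)")
    return R


def _ry(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rx(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rz(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_from_angles(angles: PoseAngles) -> np.ndarray:
    """Rotation matrix R = R_y(yaw) @ R_x(pitch) @ R_z(roll), angles in degrees."""
    a = angles.as_array()
    if not np.all(np.isfinite(a)):
        raise InvalidArgumentError("angles must be finite")
    y, p, r = np.deg2rad(a)
    return _ry(y) @ _rx(p) @ _rz(r)


def angles_from_rotation(R: np.ndarray, atol: float = 1e-9) -> PoseAngles:
    """Decompose a proper rotation into canonical yaw/pitch/roll degrees.

    With R = R_y R_x R_z the middle angle satisfies sin(pitch) = -R[1,2].
    At gimbal lock (|R[1,2]| = 1 within ``atol``) yaw and roll are coupled;
    the convention here sets roll = 0 and lets yaw absorb the free angle.
    """
    R = check_rotation(R, atol=atol)
    sp = -R[1, 2]
    if abs(sp) >= 1.0 - atol:
        pitch = math.copysign(90.0, sp)
        if sp > 0:  # pitch = +90: R[0,:2] = [cos(y-r), sin(y-r)]
            yaw = math.degrees(math.atan2(R[0, 1], R[0, 0]))
        else:       # pitch = -90: R[0,:2] = [cos(y+r), -sin(y+r)]
            yaw = math.degrees(math.atan2(-R[0, 1], R[0, 0]))
        roll = 0.0
    else:
        pitch = math.degrees(math.asin(sp))
        yaw = math.degrees(math.atan2(R[0, 2], R[2, 2]))
        roll = math.degrees(math.atan2(R[1, 0], R[1, 1]))
    return PoseAngles(float(wrap_degrees(yaw)), float(pitch), float(wrap_degrees(roll)))


def project(points: Sequence, R: np.ndarray, t: Sequence, cam: CameraModel) -> np.ndarray:
    """Perspective-project 3D model points to pixel coordinates.

    Camera coordinates are X = R @ P + t; the pixel is
    principal_point + focal_length * (X.xy / X.z).  Every point must lie
    in front of the camera (z > 0) or :class:`BehindCameraError` is raised.

    Returns an (n, 2) float array of pixel coordinates.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[1] != 3:
        raise InvalidArgumentError("points must be (n, 3)")
    t = np.asarray(t, dtype=float).reshape(3)
    X = P @ np.asarray(R, dtype=float).T + t
    z = X[:, 2]
    if np.any(z <= 0):
        raise BehindCameraError(f"{int(np.sum(z <= 0))} point(s) at z <= 0")
    pp = np.asarray(cam.principal_point, dtype=float)
    return pp + cam.focal_length * X[:, :2] / z[:, None]
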