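"""Canned desk-scale experiment setups.

These functions pin the study conditions used throughout the package's
own evaluation — the synthetic camera, pose ranges, noise levels and
sample counts — so the CLI, the test suite and the reproduction script
all run the identical experiment.

``toy_regression_dataset`` renders the pose-regression corpus: the
21-point head constellation at poses drawn uniformly from +/-60 deg yaw,
+/-40 deg pitch, +/-30 deg roll, imaged by a 64 x 64 px camera (focal
420 px, object at depth 10 model units, which makes the head fill most
of the frame) with 1 px Gaussian landmark noise.

``posit_recovery_experiment`` measures the solver's angle-recovery error
over seeded random poses with |yaw|, |pitch|, |roll| <= 60 deg at focal
800 px and depth 10.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .geometry import CameraModel, PoseAngles, project, rotation_from_angles
from .posit import CorrespondenceSet, solve_posit
from .schemes import head_scheme
from .simdata import NoiseConfig, generate_dataset, rasterize

__all__ = ["toy_regression_dataset", "posit_recovery_experiment",
           "TOY_CAMERA", "TOY_POSE_RANGES"]

#: small-frame camera for the toy regressor (64 x 64 px rasters)
TOY_CAMERA = CameraModel(focal_length=420.0, principal_point=(32.0, 32.0),
                         image_size=(64, 64))

#: pose sampling ranges for the toy regression corpus (degrees)
TOY_POSE_RANGES = {"yaw": (-60.0, 60.0), "pitch": (-40.0, 40.0),
                   "roll": (-30.0, 30.0)}


def toy_regression_dataset(
    n_train: int = 600, n_test: int = 200, seed: int = 0,
    pixel_sigma: float = 1.0,
) -> Tuple[Tuple[List[np.ndarray], np.ndarray], Tuple[List[np.ndarray], np.ndarray]]:
    """Rendered rasters + true angles, split into (train, test)."""
    n = n_train + n_test
    _, samples = generate_dataset(
        head_scheme(), n, cam=TOY_CAMERA,
        noise=NoiseConfig(pixel_sigma=pixel_sigma, dropout_prob=0.0, seed=seed),
        pose_ranges=TOY_POSE_RANGES, seed=seed)
    rasters = [rasterize(s, TOY_CAMERA) for s in samples]
    angles = np.array([s.true_pose.as_array() for s in samples])
    return ((rasters[:n_train], angles[:n_train]),
            (rasters[n_train:], angles[n_train:]))


def posit_recovery_experiment(
    n_poses: int = 100, pixel_sigma: float = 0.0, seed: int = 0,
    angle_limit: float = 60.0, focal: float = 800.0, depth: float = 10.0,
) -> dict:
    """Solve seeded random noiseless/noisy scenes; summarize recovery error.

    Returns median absolute angle error (degrees, over all three angles
    and all poses) and the median reprojection RMSE in pixels.
    """
    rng = np.random.default_rng(seed)
    scheme = head_scheme()
    cam = CameraModel(focal, (0.0, 0.0), (2 * int(focal), 2 * int(focal)))
    t = np.array([0.0, 0.0, depth])
    angle_errors = []
    rmses = []
    for _ in range(n_poses):
        truth = PoseAngles(*rng.uniform(-angle_limit, angle_limit, size=3))
        pts = project(scheme.canonical_points, rotation_from_angles(truth), t, cam)
        if pixel_sigma > 0:
            pts = pts + rng.normal(0.0, pixel_sigma, size=pts.shape)
        corr = CorrespondenceSet(scheme, pts, np.ones(len(scheme), dtype=bool))
        sol = solve_posit(corr, cam)
        rec = sol.angles
        d = np.abs((rec.as_array() - truth.as_array() + 180.0) % 360.0 - 180.0)
        angle_errors.extend(d.tolist())
        rmses.append(sol.reprojection_rmse)
    return {
        "n_poses": n_poses,
        "pixel_sigma": pixel_sigma,
        "median_angle_error_deg": float(np.median(angle_errors)),
        "median_rmse_px": float(np.median(rmses)),
        "max_rmse_px": float(np.max(rmses)),
    }
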