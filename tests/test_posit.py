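"""POSIT solver: recovery accuracy, invariants and failure modes.

The ground-truth generator (``geometry.project``) serves as the
independent forward oracle: scenes are synthesized at known poses and
the solver must recover them.  A reprojection-minimizing nonlinear
least-squares refinement provides a second, algorithm-independent route
to the same pose on small instances.
"""

import numpy as np
import pytest
from scipy.optimize import least_squares

from cowpose.errors import DegenerateGeometryError, InsufficientLandmarksError
from cowpose.geometry import (
    CameraModel,
    PoseAngles,
    project,
    rotation_from_angles,
    wrap_degrees,
)
from cowpose.posit import CorrespondenceSet, estimate_pose, solve_posit
from cowpose.schemes import LandmarkScheme


CAM = CameraModel(800.0, (0.0, 0.0), (1600, 1600))
DEPTH = np.array([0.0, 0.0, 10.0])


def scene(scheme, pose, t=DEPTH, cam=CAM, sigma=0.0, rng=None, visible=None):
    pts = project(scheme.canonical_points, rotation_from_angles(pose), t, cam)
    if sigma > 0:
        pts = pts + rng.normal(0, sigma, size=pts.shape)
    if visible is None:
        visible = np.ones(len(scheme), dtype=bool)
    return CorrespondenceSet(scheme, pts, visible)


def angle_error(a: PoseAngles, b: PoseAngles) -> float:
    return float(np.max(np.abs(wrap_degrees(a.as_array() - b.as_array()))))


class TestSolvePosit:
    def test_identity_pose_recovery(self, head):
        sol = solve_posit(scene(head, PoseAngles(0, 0, 0)), CAM)
        assert angle_error(sol.angles, PoseAngles(0, 0, 0)) < 1e-3
        assert np.max(np.abs(sol.translation - DEPTH)) < 1e-3
        assert sol.converged

    def test_noiseless_random_pose(self, head, rng):
        for _ in range(10):
            truth = PoseAngles(*rng.uniform(-60, 60, 3))
            sol = solve_posit(scene(head, truth), CAM)
            assert angle_error(sol.angles, truth) < 0.5
            assert sol.reprojection_rmse < 0.1
            assert sol.translation[2] > 0

    def test_ear_scheme_recovery(self, ear, rng):
        truth = PoseAngles(*rng.uniform(-45, 45, 3))
        sol = solve_posit(scene(ear, truth), CAM)
        assert angle_error(sol.angles, truth) < 0.5

    def test_too_few_visible_landmarks(self, head):
        visible = np.zeros(21, dtype=bool)
        visible[:3] = True
        with pytest.raises(InsufficientLandmarksError):
            solve_posit(scene(head, PoseAngles(0, 0, 0), visible=visible), CAM)

    def test_coplanar_visible_subset_rejected(self):
        # scheme is non-coplanar overall, but the visible subset is flat
        pts = np.zeros((6, 3))
        pts[:, 0] = [0, 1, 2, 0, 1, 2]
        pts[:, 1] = [0, 0, 0, 1, 1, 1.5]
        pts[5, 2] = 1.0  # one out-of-plane point keeps the scheme valid
        scheme = LandmarkScheme("mostly_flat", tuple("abcdef"), pts)
        visible = np.array([True] * 5 + [False])
        corr = scene(scheme, PoseAngles(10, 5, 0), visible=visible)
        with pytest.raises(DegenerateGeometryError):
            solve_posit(corr, CAM)

    def test_rmse_non_increasing_on_noiseless_input(self, head, rng):
        for _ in range(5):
            truth = PoseAngles(*rng.uniform(-50, 50, 3))
            sol = solve_posit(scene(head, truth), CAM)
            hist = np.array(sol.rmse_history)
            assert np.all(np.diff(hist) <= 1e-9)

    def test_scale_invariance_of_angles(self, head, rng):
        """Uniformly rescaling the model leaves angles unchanged, scales t."""
        truth = PoseAngles(25, -15, 10)
        sol1 = solve_posit(scene(head, truth), CAM)
        scaled = LandmarkScheme("head3x", head.labels,
                                head.canonical_points * 3.0,
                                head.symmetry_pairs, head.normals)
        # same image observations correspond to the scaled model at 3x depth
        pts = project(head.canonical_points,
                      rotation_from_angles(truth), DEPTH, CAM)
        corr = CorrespondenceSet(scaled, pts, np.ones(21, dtype=bool))
        sol3 = solve_posit(corr, CAM)
        assert angle_error(sol1.angles, sol3.angles) < 1e-3
        assert np.allclose(sol3.translation, 3.0 * sol1.translation, rtol=1e-3)

    def test_dropout_preserves_invariants(self, head, rng):
        truth = PoseAngles(20, -25, 15)
        for _ in range(10):
            visible = np.ones(21, dtype=bool)
            drop = rng.choice(21, size=rng.integers(0, 17), replace=False)
            visible[drop] = False
            if visible.sum() < 4:
                continue
            corr = scene(head, truth, visible=visible)
            try:
                sol = solve_posit(corr, CAM)
            except DegenerateGeometryError:
                continue  # a thin visible subset may legitimately be coplanar
            assert sol.translation[2] > 0
            assert sol.reprojection_rmse >= 0
            assert sol.iterations >= 1

    def test_accuracy_degrades_with_noise(self, head, rng):
        """Median recovery error grows with pixel noise level (seeded)."""
        levels = [0.0, 1.0, 4.0]
        medians = []
        for sigma in levels:
            errs = []
            for _ in range(30):
                truth = PoseAngles(*rng.uniform(-45, 45, 3))
                corr = scene(head, truth, sigma=sigma, rng=rng)
                errs.append(angle_error(estimate_pose(corr, CAM), truth))
            medians.append(np.median(errs))
        assert medians[0] < medians[1] < medians[2]


class TestAgainstReprojectionOracle:
    """POSIT agrees with an independent reprojection-minimizing solver."""

    def oracle(self, corr, cam, t0=DEPTH):
        model, image = corr.visible_subset()

        def residual(params):
            pose = PoseAngles(*params[:3])
            t = params[3:]
            proj = project(model, rotation_from_angles(pose), t, cam)
            return (proj - image).ravel()

        best = None
        for y0 in (-30.0, 0.0, 30.0):
            res = least_squares(residual, [y0, 0, 0, *t0], method="lm")
            if best is None or res.cost < best.cost:
                best = res
        return PoseAngles(*best.x[:3]).canonical(), best.x[3:]

    def test_noiseless_agreement(self, head, rng):
        for _ in range(5):
            truth = PoseAngles(*rng.uniform(-40, 40, 3))
            corr = scene(head, truth)
            posit_sol = solve_posit(corr, CAM)
            oracle_angles, oracle_t = self.oracle(corr, CAM)
            assert angle_error(posit_sol.angles, oracle_angles) < 1e-3
            assert np.max(np.abs(posit_sol.translation - oracle_t)) < 1e-3

    def test_noisy_agreement(self, head, rng):
        """With noise both solvers land on nearby minima (degrees apart)."""
        truth = PoseAngles(15, -20, 10)
        corr = scene(head, truth, sigma=1.0, rng=rng)
        posit_sol = solve_posit(corr, CAM)
        oracle_angles, _ = self.oracle(corr, CAM)
        assert angle_error(posit_sol.angles, oracle_angles) < 2.0


class TestEstimatePose:
    def test_monte_carlo_noiseless(self, head, rng):
        errs = []
        for _ in range(100):
            truth = PoseAngles(*rng.uniform(-60, 60, 3))
            errs.append(angle_error(estimate_pose(scene(head, truth), CAM), truth))
        assert np.median(errs) <= 0.5

    def test_monte_carlo_2px_noise(self, head, rng):
        errs = []
        for _ in range(100):
            truth = PoseAngles(*rng.uniform(-60, 60, 3))
            corr = scene(head, truth, sigma=2.0, rng=rng)
            errs.append(angle_error(estimate_pose(corr, CAM), truth))
        assert np.median(errs) <= 5.0
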