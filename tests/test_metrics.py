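"""IoU, matching, average precision and pose MAE against brute-force oracles."""

import itertools

import numpy as np
import pytest

from cowpose.errors import InvalidArgumentError, UndefinedMetricError
from cowpose.geometry import PoseAngles
from cowpose.metrics import (
    BoundingBox,
    DetectionResult,
    average_precision,
    iou,
    mae_pose,
    mask_iou,
    match_and_score,
)


def pixel_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Integer-box IoU by literal pixel enumeration (half-open convention)."""
    pa = {(x, y) for x in range(int(a.x0), int(a.x1))
          for y in range(int(a.y0), int(a.y1))}
    pb = {(x, y) for x in range(int(b.x0), int(b.x1))
          for y in range(int(b.y0), int(b.y1))}
    return len(pa & pb) / len(pa | pb)


class TestIou:
    def test_identical(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(BoundingBox(0, 0, 5, 5), BoundingBox(10, 10, 15, 15)) == 0.0

    def test_half_overlap(self):
        v = iou(BoundingBox(0, 0, 10, 10), BoundingBox(5, 0, 15, 10))
        assert v == pytest.approx(50 / 150)

    def test_against_pixel_enumeration(self, rng):
        for _ in range(100):
            x0, y0 = rng.integers(0, 20, 2)
            a = BoundingBox(x0, y0, x0 + rng.integers(1, 15),
                            y0 + rng.integers(1, 15))
            x0, y0 = rng.integers(0, 20, 2)
            b = BoundingBox(x0, y0, x0 + rng.integers(1, 15),
                            y0 + rng.integers(1, 15))
            assert iou(a, b) == pytest.approx(pixel_iou(a, b), abs=1e-12)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            vals = rng.uniform(0, 50, 8)
            a = BoundingBox(vals[0], vals[1], vals[0] + vals[2] + 1,
                            vals[1] + vals[3] + 1)
            b = BoundingBox(vals[4], vals[5], vals[4] + vals[6] + 1,
                            vals[5] + vals[7] + 1)
            assert iou(a, b) == pytest.approx(iou(b, a))
            assert 0.0 <= iou(a, b) <= 1.0

    def test_degenerate_box_rejected(self):
        with pytest.raises(InvalidArgumentError):
            BoundingBox(5, 5, 5, 10)

    def test_mask_iou_squares(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        assert mask_iou(sq, sq) == pytest.approx(1.0)
        assert mask_iou(sq, sq + [5, 0]) == pytest.approx(50 / 150)


def brute_force_match(preds, truths, thresh):
    """Lexicographic-optimal one-to-one matching in descending score order.

    Enumerates every injective assignment of predictions to truths whose
    pairs clear the IoU threshold and keeps the one whose per-prediction
    IoU sequence (score order, unmatched = -1) is lexicographically
    largest — the matching a score-priority greedy rule defines, found
    by exhaustive search instead of greedily.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    best_key, best = None, []
    choices = [list(range(len(truths))) + [None]] * len(order)
    for assign in itertools.product(*choices):
        used = [t for t in assign if t is not None]
        if len(used) != len(set(used)):
            continue
        key, pairs, ok = [], [], True
        for i, t in zip(order, assign):
            if t is None:
                key.append(-1.0)
                continue
            v = iou(preds[i].box, truths[t])
            if v < thresh:
                ok = False
                break
            key.append(v)
            pairs.append((i, t))
        if ok and (best_key is None or key > best_key):
            best_key, best = key, pairs
    return best


class TestMatchAndScore:
    def test_worked_example(self):
        """5 ground-truth objects, 3 detections, 2 correct."""
        truths = [[BoundingBox(i * 20, 0, i * 20 + 10, 10) for i in range(5)]]
        preds = [[
            DetectionResult(BoundingBox(0, 0, 10, 10), 0.9),     # TP
            DetectionResult(BoundingBox(20, 0, 30, 10), 0.8),    # TP
            DetectionResult(BoundingBox(200, 0, 210, 10), 0.7),  # FP
        ]]
        rep = match_and_score(preds, truths)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 5)
        assert rep.tp == 2 and rep.fp == 1 and rep.fn == 3

    def test_perfect_detections(self):
        boxes = [BoundingBox(0, 0, 10, 10), BoundingBox(20, 20, 40, 40)]
        rep = match_and_score([[DetectionResult(b, 1.0) for b in boxes]],
                              [boxes])
        assert rep.precision == 1.0 and rep.recall == 1.0 and rep.mAP == 1.0

    def test_empty_inputs_degenerate(self):
        rep = match_and_score([[]], [[]])
        assert rep.degenerate
        assert rep.precision == 0.0 and rep.recall == 0.0

    def test_matches_one_to_one(self):
        truth = [BoundingBox(0, 0, 10, 10)]
        preds = [DetectionResult(BoundingBox(0, 0, 10, 10), 0.9),
                 DetectionResult(BoundingBox(1, 0, 11, 10), 0.8)]
        rep = match_and_score([preds], [truth])
        assert rep.tp == 1 and rep.fp == 1
        assert len(rep.matches[0]) == 1

    def test_image_order_permutation_invariance(self, rng):
        imgs_t, imgs_p = [], []
        for _ in range(6):
            t = [BoundingBox(*s) for s in
                 [(x, y, x + 10, y + 10) for x, y in rng.integers(0, 40, (2, 2))]]
            p = [DetectionResult(BoundingBox(x, y, x + 10, y + 10),
                                 float(rng.uniform(0.1, 1.0)))
                 for x, y in rng.integers(0, 40, (2, 2))]
            imgs_t.append(t)
            imgs_p.append(p)
        rep1 = match_and_score(imgs_p, imgs_t)
        perm = rng.permutation(6)
        rep2 = match_and_score([imgs_p[i] for i in perm],
                               [imgs_t[i] for i in perm])
        assert rep1.precision == pytest.approx(rep2.precision)
        assert rep1.recall == pytest.approx(rep2.recall)
        assert rep1.mAP == pytest.approx(rep2.mAP)

    def test_against_brute_force_enumeration(self, rng):
        """Greedy matcher equals exhaustive score-priority optimum, <=3x3."""
        for trial in range(60):
            nt, npred = rng.integers(0, 4), rng.integers(0, 4)
            truths = [BoundingBox(x, y, x + rng.integers(4, 12),
                                  y + rng.integers(4, 12))
                      for x, y in rng.integers(0, 25, (nt, 2))]
            preds = [DetectionResult(
                BoundingBox(x, y, x + rng.integers(4, 12),
                            y + rng.integers(4, 12)),
                float(rng.uniform(0.1, 1.0)))
                for x, y in rng.integers(0, 25, (npred, 2))]
            rep = match_and_score([preds], [truths], iou_thresh=0.3)
            expected = brute_force_match(preds, truths, 0.3)
            assert rep.tp == len(expected)
            assert sorted(rep.matches[0]) == sorted(expected)


def brute_force_ap(flags, total_truths):
    """Direct PR-curve construction: max-precision-at-recall>=r rectangles."""
    flags = list(flags)
    pts = []
    tp = 0
    for i, ok in enumerate(flags, start=1):
        tp += ok
        pts.append((tp / total_truths, tp / i))
    ap, r_prev = 0.0, 0.0
    for r, _ in pts:
        p_at = max((p for rr, p in pts if rr >= r), default=0.0)
        ap += (r - r_prev) * p_at
        r_prev = r
    return ap


class TestAveragePrecision:
    def test_all_tp(self):
        assert average_precision([True] * 4, 4) == pytest.approx(1.0)

    def test_interpolated_example(self):
        flags = [True, False, True]
        assert average_precision(flags, 3) == pytest.approx(
            brute_force_ap(flags, 3))
        assert average_precision(flags, 3) == pytest.approx(5 / 9)

    def test_single_object_degenerate_case(self):
        assert average_precision([True], 1) == pytest.approx(1.0)

    def test_exhaustive_small_rankings(self):
        for n in range(1, 7):
            for flags in itertools.product([True, False], repeat=n):
                total = max(sum(flags), 1) + 1
                assert average_precision(flags, total) == pytest.approx(
                    brute_force_ap(flags, total), abs=1e-12)

    def test_zero_truths_undefined(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([True], 0)


class TestMaePose:
    def test_identical_lists(self):
        poses = [PoseAngles(10, 20, 30), PoseAngles(-5, 0, 90)]
        assert mae_pose(poses, poses) == 0.0
        assert mae_pose(poses, poses, norm="l2") == 0.0

    def test_three_four_five(self):
        pred = [PoseAngles(3, 4, 0)]
        truth = [PoseAngles(0, 0, 0)]
        assert mae_pose(pred, truth, norm="l2") == pytest.approx(5.0)
        assert mae_pose(pred, truth, norm="per-angle") == pytest.approx(7 / 3)

    def test_wrapping_near_180(self):
        pred = [PoseAngles(179, 0, 0)]
        truth = [PoseAngles(-179, 0, 0)]
        assert mae_pose(pred, truth) == pytest.approx(2 / 3)
        assert mae_pose(pred, truth, norm="l2") == pytest.approx(2.0)

    def test_non_negative_and_zero_iff_equal(self, rng):
        for _ in range(20):
            a = [PoseAngles(*rng.uniform(-179, 179, 3)) for _ in range(5)]
            b = [PoseAngles(*rng.uniform(-179, 179, 3)) for _ in range(5)]
            assert mae_pose(a, b) >= 0
            assert mae_pose(a, b, norm="l2") >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mae_pose([PoseAngles(0, 0, 0)], [])
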