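"""Detection and pose evaluation: IoU, precision/recall, mAP, pose MAE.

Detection correctness follows the standard protocol: a prediction is a
true positive when its intersection-over-union with an unmatched
ground-truth box reaches the threshold (0.5 by default), matching
greedily in descending confidence order (COCO-style one-to-one
matching).  In the one-object-one-prediction-per-image regime the
interpolated average precision degenerates to precision at the fixed
threshold, so a single summary number stands in for the whole PR curve.

Pose error is the mean absolute error in degrees, with per-component
differences wrapped to (-180, 180] before taking magnitudes.  Two norms
are offered: ``per-angle`` (mean of |dyaw|, |dpitch|, |droll| per image,
then mean over images — the convention of the human head-pose benchmarks
this metric is usually compared against) and ``l2`` (mean Euclidean norm
of the per-image difference vector).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Polygon

from .errors import InvalidArgumentError, UndefinedMetricError
from .geometry import PoseAngles, wrap_degrees

__all__ = [
    "BoundingBox",
    "DetectionResult",
    "EvalReport",
    "iou",
    "mask_iou",
    "match_and_score",
    "average_precision",
    "mae_pose",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, half-open: [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self):
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise InvalidArgumentError(
                f"degenerate box ({self.x0}, {self.y0}, {self.x1}, {self.y1})")

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass(frozen=True)
class DetectionResult:
    """A scored detection: box, confidence in [0, 1], optional mask polygon."""

    box: BoundingBox
    score: float = 1.0
    mask_polygon: Optional[np.ndarray] = None  # (k, 2) pixel vertices

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise InvalidArgumentError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class EvalReport:
    """Precision, recall and mAP at a fixed IoU threshold, plus matches.

    ``matches`` lists per image the (prediction index, truth index) pairs
    that were counted as true positives.  ``degenerate`` flags the
    empty-input case where precision/recall default to 0.
    """

    precision: float
    recall: float
    mAP: float
    matches: Tuple[Tuple[Tuple[int, int], ...], ...]
    tp: int
    fp: int
    fn: int
    degenerate: bool = False


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def mask_iou(a: Sequence, b: Sequence) -> float:
    """IoU of two simple polygons (pixel-vertex arrays), via exact areas."""
    pa, pb = Polygon(np.asarray(a, float)), Polygon(np.asarray(b, float))
    if not (pa.is_valid and pb.is_valid):
        raise InvalidArgumentError("mask polygons must be simple/valid")
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return inter / union if union > 0 else 0.0


def _match_image(
    preds: Sequence[DetectionResult],
    truths: Sequence[BoundingBox],
    iou_thresh: float,
) -> Tuple[List[Tuple[int, int]], List[Tuple[float, bool]]]:
    """Greedy one-to-one matching for one image.

    Returns the TP (pred, truth) index pairs and, for every prediction,
    its (score, is_tp) flag for the ranked AP computation.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    unmatched = set(range(len(truths)))
    pairs: List[Tuple[int, int]] = []
    flags: List[Tuple[float, bool]] = []
    for i in order:
        best_j, best_iou = -1, 0.0
        for j in unmatched:
            v = iou(preds[i].box, truths[j])
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_thresh:
            unmatched.discard(best_j)
            pairs.append((i, best_j))
            flags.append((preds[i].score, True))
        else:
            flags.append((preds[i].score, False))
    return pairs, flags


def match_and_score(
    preds: Sequence[Sequence[DetectionResult]],
    truths: Sequence[Sequence[BoundingBox]],
    iou_thresh: float = 0.5,
) -> EvalReport:
    """Evaluate detections against ground truth across a set of images.

    ``preds[i]`` and ``truths[i]`` belong to image i.  Matching is greedy
    in descending score order per image, one-to-one; a prediction is a TP
    iff its best unmatched truth reaches ``iou_thresh``.
    """
    if len(preds) != len(truths):
        raise InvalidArgumentError("preds and truths must cover the same images")
    all_pairs = []
    all_flags: List[Tuple[float, bool]] = []
    total_truths = 0
    for p_img, t_img in zip(preds, truths):
        pairs, flags = _match_image(p_img, t_img, iou_thresh)
        all_pairs.append(tuple(pairs))
        all_flags.extend(flags)
        total_truths += len(t_img)

    tp = sum(1 for _, ok in all_flags if ok)
    fp = len(all_flags) - tp
    fn = total_truths - tp
    degenerate = len(all_flags) == 0 or total_truths == 0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    if total_truths > 0 and all_flags:
        ranked = [ok for _, ok in sorted(all_flags, key=lambda sf: -sf[0])]
        ap = average_precision(ranked, total_truths)
    else:
        ap = 0.0
    return EvalReport(precision=precision, recall=recall, mAP=ap,
                      matches=tuple(all_pairs), tp=tp, fp=fp, fn=fn,
                      degenerate=degenerate)


def average_precision(ranked_flags: Sequence[bool], total_truths: int) -> float:
    """All-points interpolated AP from score-ranked TP/FP flags.

    Area under the running-maximum (envelope) of precision as a function
    of recall.  With one object and one prediction per image this reduces
    to precision at the operating threshold.
    """
    if total_truths <= 0:
        raise UndefinedMetricError("AP undefined with zero ground-truth objects")
    flags = np.asarray(ranked_flags, dtype=bool)
    if flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    n_pred = np.arange(1, flags.size + 1)
    precision = tp_cum / n_pred
    recall = tp_cum / total_truths
    # precision envelope (running max from the right), then rectangle sum
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def mae_pose(
    preds: Sequence[PoseAngles],
    truths: Sequence[PoseAngles],
    norm: str = "per-angle",
) -> float:
    """Mean absolute pose error in degrees.

    Differences are wrapped to (-180, 180] per component.  ``per-angle``
    averages the three absolute component errors per image then over
    images; ``l2`` averages the Euclidean norm of the per-image
    difference vector, MAE = (1/N) sum_n ||pred_n - truth_n||.
    """
    if len(preds) != len(truths) or len(preds) == 0:
        raise InvalidArgumentError("need equal, non-empty prediction/truth lists")
    if norm not in ("per-angle", "l2"):
        raise InvalidArgumentError(f"unknown norm {norm!r}")
    P = np.array([p.as_array() for p in preds])
    T = np.array([t.as_array() for t in truths])
    d = -wrap_degrees(T - P)  # wrap to [-180, 180); negate -> (-180, 180]
    if norm == "per-angle":
        return float(np.mean(np.abs(d)))
    return float(np.mean(np.linalg.norm(d, axis=1)))
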