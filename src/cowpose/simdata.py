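"""Synthetic pose/detection fixtures: projected landmark scenes.

No public image set exists for cattle head/ear pose work (the underlying
field data is private), so this module generates fully synthetic stand-ins:
the committed canonical landmark constellation is placed at a known pose,
perspective-projected through a pinhole camera, perturbed with Gaussian
pixel noise, and thinned by random dropout plus geometric self-occlusion.
Each sample carries its ground truth (pose, translation, per-landmark
visibility), a padded bounding box, a convex-hull mask polygon and an
optional grayscale raster, which is enough to exercise the full
annotate-detect-evaluate pipeline end to end.

Self-occlusion uses the committed per-landmark outward normals: a
landmark is hidden when its rotated normal faces away from the camera
(positive component along the optical axis).  Datasets are split
60/20/20 into train/validation/test by a seeded shuffle.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .errors import (
    CannotRasterizeError,
    EmptySampleError,
    InvalidArgumentError,
)
from .geometry import CameraModel, PoseAngles, project, rotation_from_angles
from .metrics import BoundingBox
from .schemes import LandmarkScheme

__all__ = [
    "NoiseConfig",
    "SyntheticSample",
    "DatasetManifest",
    "generate_sample",
    "generate_dataset",
    "rasterize",
    "DEFAULT_POSE_RANGES",
]

#: default uniform pose sampling ranges (degrees): (low, high) per angle.
#: The pose distribution of real herd footage is unknown; these cover the
#: orientations a grazing/standing animal plausibly presents to a camera.
DEFAULT_POSE_RANGES = {"yaw": (-90.0, 90.0), "pitch": (-60.0, 60.0),
                       "roll": (-60.0, 60.0)}

#: fraction of the tight landmark hull added as padding on every side
BBOX_PAD = 0.05


@dataclass(frozen=True)
class NoiseConfig:
    """Observation noise: pixel jitter sigma, dropout probability, seed."""

    pixel_sigma: float = 0.0
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_sigma < 0:
            raise InvalidArgumentError("pixel_sigma must be >= 0")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise InvalidArgumentError("dropout_prob must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSample:
    """One synthetic scene with full ground truth."""

    sample_id: str
    scheme_name: str
    true_pose: PoseAngles
    true_translation: np.ndarray
    landmarks2d: np.ndarray          # (n, 2) pixels, noise applied
    visibility: np.ndarray           # (n,) bool
    bbox: BoundingBox
    mask_polygon: np.ndarray         # (k, 2) convex hull vertices
    image: Optional[np.ndarray] = None


@dataclass(frozen=True)
class DatasetManifest:
    """Split-tagged records for a generated dataset.

    ``records`` is a DataFrame with columns (sample_id, split, yaw_deg,
    pitch_deg, roll_deg, corr_file, via_file, image_file); splits are
    disjoint and exhaustive.
    """

    records: pd.DataFrame
    seed: int

    def split_counts(self) -> dict:
        return self.records["split"].value_counts().to_dict()

    def to_csv(self) -> str:
        return self.records.to_csv(index=False, float_format="%.9g",
                                   lineterminator="\n")


def generate_sample(
    scheme: LandmarkScheme,
    pose: PoseAngles,
    translation: Sequence,
    cam: CameraModel,
    noise: NoiseConfig = NoiseConfig(),
    sample_id: str = "sample",
    rng: Optional[np.random.Generator] = None,
) -> SyntheticSample:
    """Project ``scheme`` at ``pose`` and package it with ground truth.

    Visibility = (not randomly dropped) AND (not self-occluded).  The
    bounding box is the axis-aligned hull of the visible landmarks padded
    5% per side; the mask polygon is their convex hull.  Raises
    :class:`EmptySampleError` when nothing remains visible, and
    :class:`InvalidArgumentError` when a visible landmark falls outside
    the image.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    t = np.asarray(translation, dtype=float)
    if t[2] <= 0:
        raise InvalidArgumentError("translation must put the object at z > 0")
    R = rotation_from_angles(pose)
    exact = project(scheme.canonical_points, R, t, cam)

    # geometric self-occlusion: rotated outward normal facing away
    facing = (scheme.normals @ R.T)[:, 2] if scheme.normals is not None \
        else np.full(len(scheme), -1.0)
    visible = facing < 0.0
    # random dropout (annotator misses / obstructions)
    dropped = rng.random(len(scheme)) < noise.dropout_prob
    visible &= ~dropped
    if not visible.any():
        raise EmptySampleError("every landmark was dropped or self-occluded")

    pts = exact.copy()
    if noise.pixel_sigma > 0:
        pts = pts + rng.normal(0.0, noise.pixel_sigma, size=pts.shape)

    w, h = cam.image_size
    vis_pts = pts[visible]
    if (vis_pts[:, 0].min() < 0 or vis_pts[:, 0].max() >= w
            or vis_pts[:, 1].min() < 0 or vis_pts[:, 1].max() >= h):
        raise InvalidArgumentError("projected landmarks fall outside the image")

    x0, y0 = vis_pts.min(axis=0)
    x1, y1 = vis_pts.max(axis=0)
    pad_x = max(BBOX_PAD * (x1 - x0), 1.0)
    pad_y = max(BBOX_PAD * (y1 - y0), 1.0)
    bbox = BoundingBox(x0 - pad_x, y0 - pad_y, x1 + pad_x, y1 + pad_y)

    if len(vis_pts) >= 3:
        hull = ConvexHull(vis_pts)
        mask = vis_pts[hull.vertices]
    else:
        mask = vis_pts
    return SyntheticSample(
        sample_id=sample_id,
        scheme_name=scheme.name,
        true_pose=pose,
        true_translation=t,
        landmarks2d=pts,
        visibility=visible,
        bbox=bbox,
        mask_polygon=mask,
    )


def _sample_pose(rng: np.random.Generator, pose_ranges: dict) -> PoseAngles:
    vals = [rng.uniform(*pose_ranges[k]) for k in ("yaw", "pitch", "roll")]
    return PoseAngles(*vals)


def generate_dataset(
    scheme: LandmarkScheme,
    n: int,
    cam: Optional[CameraModel] = None,
    noise: NoiseConfig = NoiseConfig(),
    pose_ranges: Optional[dict] = None,
    translation: Sequence = (0.0, 0.0, 10.0),
    split: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> Tuple[DatasetManifest, List[SyntheticSample]]:
    """Generate ``n`` samples with uniformly drawn poses and a 60/20/20 split.

    Split sizes are round(n * p) for validation and test with the
    remainder assigned to train; assignment order is a seeded shuffle.
    A drawn pose that self-occludes below 4 visible landmarks is redrawn
    (the solver needs at least 4).
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if abs(sum(split) - 1.0) > 1e-9 or any(p < 0 for p in split):
        raise InvalidArgumentError("split proportions must be >= 0 and sum to 1")
    if cam is None:
        cam = CameraModel.default()
    if pose_ranges is None:
        pose_ranges = DEFAULT_POSE_RANGES
    rng = np.random.default_rng(seed)

    samples: List[SyntheticSample] = []
    for i in range(n):
        for _attempt in range(100):
            pose = _sample_pose(rng, pose_ranges)
            try:
                s = generate_sample(scheme, pose, translation, cam, noise,
                                    sample_id=f"{scheme.name}_{i:05d}", rng=rng)
            except EmptySampleError:
                continue
            if s.visibility.sum() >= 4:
                break
        else:  # pragma: no cover - ranges would have to be pathological
            raise EmptySampleError("could not draw a usable pose in 100 tries")
        samples.append(s)

    n_val = round(n * split[1])
    n_test = round(n * split[2])
    n_train = n - n_val - n_test
    tags = (["train"] * n_train) + (["val"] * n_val) + (["test"] * n_test)
    order = np.random.default_rng(seed + 1).permutation(n)
    split_of = {samples[idx].sample_id: tags[k] for k, idx in enumerate(order)}

    rows = [{
        "sample_id": s.sample_id,
        "split": split_of[s.sample_id],
        "yaw_deg": s.true_pose.yaw,
        "pitch_deg": s.true_pose.pitch,
        "roll_deg": s.true_pose.roll,
        "corr_file": f"{s.sample_id}.corr.csv",
        "via_file": f"{s.sample_id}.via.json",
        "image_file": f"{s.sample_id}.png",
    } for s in samples]
    manifest = DatasetManifest(records=pd.DataFrame(rows), seed=seed)
    return manifest, samples


def rasterize(sample: SyntheticSample, cam: CameraModel,
              blob_sigma: float = 2.0) -> np.ndarray:
    """Render a sample as a deterministic grayscale float raster in [0, 1].

    The mask polygon is filled mid-gray on black, and each visible
    landmark becomes a Gaussian blob (sigma 2 px) whose peak intensity
    decreases with landmark index so blobs stay distinguishable.  Blobs
    are composited over the mask with a pixelwise maximum, so every blob
    center is the local intensity peak regardless of where it sits
    relative to the mask boundary.  Pixels outside the padded bounding
    box remain 0.
    """
    if int(sample.visibility.sum()) < 3:
        raise CannotRasterizeError("need >= 3 visible landmarks to rasterize")
    w, h = cam.image_size
    img = np.zeros((h, w), dtype=float)

    from PIL import Image, ImageDraw
    mask_im = Image.new("F", (w, h), 0.0)
    draw = ImageDraw.Draw(mask_im)
    draw.polygon([tuple(p) for p in sample.mask_polygon], fill=0.35)
    img += np.asarray(mask_im)

    ys = np.arange(h)[:, None]
    xs = np.arange(w)[None, :]
    vis_idx = np.flatnonzero(sample.visibility)
    for rank, i in enumerate(vis_idx):
        cx, cy = sample.landmarks2d[i]
        amp = 0.9 - 0.4 * rank / max(len(vis_idx) - 1, 1)
        lo_x, hi_x = int(max(cx - 8, 0)), int(min(cx + 9, w))
        lo_y, hi_y = int(max(cy - 8, 0)), int(min(cy + 9, h))
        gx = xs[:, lo_x:hi_x] - cx
        gy = ys[lo_y:hi_y] - cy
        blob = amp * np.exp(-(gx ** 2 + gy ** 2) / (2.0 * blob_sigma ** 2))
        img[lo_y:hi_y, lo_x:hi_x] = np.maximum(img[lo_y:hi_y, lo_x:hi_x], blob)

    # nothing outside the padded bbox
    bb = sample.bbox
    keep = np.zeros_like(img, dtype=bool)
    keep[int(max(bb.y0, 0)):int(np.ceil(min(bb.y1, h))),
         int(max(bb.x0, 0)):int(np.ceil(min(bb.x1, w)))] = True
    img[~keep] = 0.0
    return np.clip(img, 0.0, 1.0)
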