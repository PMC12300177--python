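"""Readers and writers for the annotation formats the pipeline touches.

* VIA (VGG Image Annotator) 2.x project JSON, restricted to polygon and
  rectangle regions — the dialect used for detection ground truth.
  Other shapes are rejected loudly.
* Pose record CSV: columns (image_id, yaw_deg, pitch_deg, roll_deg);
  angles are re-canonicalized on read with a warning when wrapping
  actually changed a value.
* Dataset manifest CSV (the simdata dialect).
* 2D-3D correspondence CSV: columns (label, x_px, y_px, visible).
* Detection CSV: columns (sample_id, x0, y0, x1, y1[, score]).

All writers are deterministic (sorted JSON keys, fixed float format) so
repeated runs produce byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError, UnsupportedShapeError
from .geometry import PoseAngles
from .metrics import BoundingBox, DetectionResult
from .posit import CorrespondenceSet
from .schemes import LandmarkScheme

__all__ = [
    "ViaRegion",
    "ViaAnnotation",
    "read_via_project",
    "write_via_project",
    "read_pose_records",
    "write_pose_records",
    "read_manifest",
    "write_manifest",
    "read_correspondences",
    "write_correspondences",
    "read_detections",
    "write_detections",
]

MANIFEST_COLUMNS = ["sample_id", "split", "yaw_deg", "pitch_deg", "roll_deg",
                    "corr_file", "via_file", "image_file"]
POSE_COLUMNS = ["image_id", "yaw_deg", "pitch_deg", "roll_deg"]


@dataclass(frozen=True)
class ViaRegion:
    """One annotated region: a polygon (>= 3 vertices) or a rect box."""

    shape_type: str                      # "polygon" | "rect"
    points: Optional[np.ndarray] = None  # (k, 2) for polygons
    box: Optional[BoundingBox] = None    # for rects
    attributes: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.shape_type == "polygon":
            pts = np.asarray(self.points, dtype=float)
            if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
                raise InvalidArgumentError("polygon needs >= 3 (x, y) vertices")
            object.__setattr__(self, "points", pts)
        elif self.shape_type == "rect":
            if self.box is None:
                raise InvalidArgumentError("rect region needs a box")
        else:
            raise UnsupportedShapeError(
                f"unsupported region shape {self.shape_type!r}")


@dataclass(frozen=True)
class ViaAnnotation:
    image_id: str
    regions: Tuple[ViaRegion, ...] = ()


def read_via_project(text: str) -> List[ViaAnnotation]:
    """Parse VIA 2.x project JSON into annotations.

    Accepts both a full project file (with ``_via_img_metadata``) and a
    bare image-metadata dict.  Raises :class:`UnsupportedShapeError` for
    any region shape other than polygon/rect, naming the shape.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise InvalidArgumentError(f"malformed VIA JSON: {e}") from e
    meta = doc.get("_via_img_metadata", doc)
    out = []
    for key in sorted(meta):
        entry = meta[key]
        if not isinstance(entry, dict) or "filename" not in entry:
            raise InvalidArgumentError(f"malformed VIA image entry {key!r}")
        regions = []
        for reg in entry.get("regions", []):
            shape = reg.get("shape_attributes", {})
            name = shape.get("name")
            attrs = tuple(sorted((str(k), str(v)) for k, v in
                                 reg.get("region_attributes", {}).items()))
            if name == "polygon":
                pts = np.column_stack([shape["all_points_x"],
                                       shape["all_points_y"]]).astype(float)
                regions.append(ViaRegion("polygon", points=pts, attributes=attrs))
            elif name == "rect":
                x, y = float(shape["x"]), float(shape["y"])
                w, h = float(shape["width"]), float(shape["height"])
                regions.append(ViaRegion(
                    "rect", box=BoundingBox(x, y, x + w, y + h), attributes=attrs))
            else:
                raise UnsupportedShapeError(
                    f"unsupported VIA region shape {name!r}")
        out.append(ViaAnnotation(entry["filename"], tuple(regions)))
    return out


def write_via_project(annotations: Sequence[ViaAnnotation]) -> str:
    """Serialize annotations to VIA 2.x project JSON (deterministic)."""
    meta: Dict[str, dict] = {}
    for ann in annotations:
        regions = []
        for reg in ann.regions:
            if reg.shape_type == "polygon":
                shape = {
                    "name": "polygon",
                    "all_points_x": [float(x) for x in reg.points[:, 0]],
                    "all_points_y": [float(y) for y in reg.points[:, 1]],
                }
            else:
                b = reg.box
                shape = {"name": "rect", "x": float(b.x0), "y": float(b.y0),
                         "width": float(b.x1 - b.x0),
                         "height": float(b.y1 - b.y0)}
            regions.append({"shape_attributes": shape,
                            "region_attributes": dict(reg.attributes)})
        meta[ann.image_id] = {"filename": ann.image_id, "size": -1,
                              "regions": regions, "file_attributes": {}}
    return json.dumps({"_via_img_metadata": meta}, sort_keys=True, indent=1)


# -- CSV tables ---------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{what} is missing required column {c!r}")


def read_pose_records(text_or_path) -> List[Tuple[str, PoseAngles]]:
    """Read (image_id, PoseAngles) rows; angles canonicalized on read.

    Emits a UserWarning naming each image whose stored angles were
    outside the canonical ranges and had to be wrapped.
    """
    df = pd.read_csv(text_or_path)
    _require_columns(df, POSE_COLUMNS, "pose record file")
    out = []
    for _, row in df.iterrows():
        raw = PoseAngles(float(row.yaw_deg), float(row.pitch_deg),
                         float(row.roll_deg))
        canon = raw.canonical()
        if np.max(np.abs(raw.as_array() - canon.as_array())) > 1e-9:
            warnings.warn(
                f"pose for {row.image_id!r} was outside canonical ranges; "
                "wrapped", stacklevel=2)
        out.append((str(row.image_id), canon))
    return out


def write_pose_records(records: Sequence[Tuple[str, PoseAngles]]) -> str:
    df = pd.DataFrame(
        [{"image_id": i, "yaw_deg": a.yaw, "pitch_deg": a.pitch,
          "roll_deg": a.roll} for i, a in records], columns=POSE_COLUMNS)
    return df.to_csv(index=False, float_format="%.12g", lineterminator="\n")


def read_manifest(text_or_path) -> pd.DataFrame:
    df = pd.read_csv(text_or_path)
    _require_columns(df, MANIFEST_COLUMNS, "manifest")
    return df


def write_manifest(df: pd.DataFrame) -> str:
    _require_columns(df, MANIFEST_COLUMNS, "manifest")
    return df.to_csv(index=False, float_format="%.9g", lineterminator="\n")


def read_correspondences(text_or_path, scheme: LandmarkScheme) -> CorrespondenceSet:
    """Read a (label, x_px, y_px, visible) CSV into a CorrespondenceSet.

    Rows are matched to scheme labels; labels absent from the file are
    marked invisible.
    """
    df = pd.read_csv(text_or_path)
    _require_columns(df, ["label", "x_px", "y_px", "visible"],
                     "correspondence file")
    pts = np.zeros((len(scheme), 2))
    vis = np.zeros(len(scheme), dtype=bool)
    index = {lab: i for i, lab in enumerate(scheme.labels)}
    for _, row in df.iterrows():
        lab = str(row.label)
        if lab not in index:
            raise SchemaError(f"unknown landmark label {lab!r}")
        i = index[lab]
        pts[i] = (float(row.x_px), float(row.y_px))
        vis[i] = bool(row.visible)
    return CorrespondenceSet(scheme, pts, vis)


def write_correspondences(corr: CorrespondenceSet) -> str:
    df = pd.DataFrame({
        "label": list(corr.scheme.labels),
        "x_px": corr.image_points[:, 0],
        "y_px": corr.image_points[:, 1],
        "visible": corr.visibility.astype(int),
    })
    return df.to_csv(index=False, float_format="%.9g", lineterminator="\n")


def read_detections(text_or_path, scored: bool = False):
    """Read per-image boxes: {sample_id: [...]}; DetectionResult if scored."""
    df = pd.read_csv(text_or_path)
    cols = ["sample_id", "x0", "y0", "x1", "y1"] + (["score"] if scored else [])
    _require_columns(df, cols, "detection file")
    out: Dict[str, list] = {}
    for _, row in df.iterrows():
        box = BoundingBox(float(row.x0), float(row.y0),
                          float(row.x1), float(row.y1))
        item = DetectionResult(box, float(row.score)) if scored else box
        out.setdefault(str(row.sample_id), []).append(item)
    return out


def write_detections(per_image: Dict[str, Sequence], scored: bool = False) -> str:
    rows = []
    for sid in sorted(per_image):
        for item in per_image[sid]:
            box = item.box if scored else item
            row = {"sample_id": sid, "x0": box.x0, "y0": box.y0,
                   "x1": box.x1, "y1": box.y1}
            if scored:
                row["score"] = item.score
            rows.append(row)
    cols = ["sample_id", "x0", "y0", "x1", "y1"] + (["score"] if scored else [])
    return pd.DataFrame(rows, columns=cols).to_csv(
        index=False, float_format="%.9g", lineterminator="\n")
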