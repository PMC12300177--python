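"""Landmark scheme registry: 21-point cattle head, 13-point left ear.

The original 3D models of the cow head and left ear are not published,
so this module commits its own canonical coordinates as versioned fixture
data: the head landmarks sit on a stylized bovine head (unit head length
front-to-back, origin at the landmark centroid, bilaterally symmetric
about the x = 0 plane), and the ear landmarks on a curved elliptical
paraboloid patch running from apex to base.  All geometric tests in this
package reference these committed values.

Frame convention matches :mod:`cowpose.geometry`: x right, y down,
z into the scene — at the frontal (0, 0, 0) pose the muzzle points
toward the camera (negative z), and every committed landmark lies on a
camera-facing surface.

Each landmark also carries an outward unit normal, used by the synthetic
generator to decide self-occlusion.  Head normals radiate from a
reference point placed behind the skull; ear normals are the inward
(camera-facing) normals of the paraboloid patch.

The head scheme is derived from the 21-landmark human-face annotation
scheme (AFLW); :func:`aflw_mapping` records the full human-to-cattle
correspondence, including which rows are exact 1:1 matches and which are
closest anatomical analogs.  Two published mapping rows carry the same
cattle label ("Left Eye Right Lower Corner"); they are disambiguated
here with "(medial)"/"(lateral)" suffixes so the 21 labels stay unique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Tuple

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "LandmarkScheme",
    "MappingEntry",
    "head_scheme",
    "ear_scheme",
    "aflw_mapping",
]


@dataclass(frozen=True)
class LandmarkScheme:
    """An ordered, named 3D landmark constellation in model units."""

    name: str
    labels: Tuple[str, ...]
    canonical_points: np.ndarray          # (n, 3) float
    symmetry_pairs: Tuple[Tuple[str, str], ...] = ()
    normals: np.ndarray = None            # (n, 3) unit outward normals

    def __post_init__(self):
        pts = np.asarray(self.canonical_points, dtype=float)
        object.__setattr__(self, "canonical_points", pts)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "symmetry_pairs",
                           tuple((a, b) for a, b in self.symmetry_pairs))
        if self.normals is not None:
            nrm = np.asarray(self.normals, dtype=float)
            object.__setattr__(self, "normals", nrm)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise InvalidArgumentError(f"{self.name}: duplicate labels")
        if self.canonical_points.shape != (n, 3):
            raise InvalidArgumentError(f"{self.name}: need one 3D point per label")
        if not np.all(np.isfinite(self.canonical_points)):
            raise InvalidArgumentError(f"{self.name}: non-finite coordinates")
        if self.coplanarity_ratio() <= 1e-3:
            raise InvalidArgumentError(f"{self.name}: landmarks are near-coplanar")
        idx = {lab: i for i, lab in enumerate(self.labels)}
        for left, right in self.symmetry_pairs:
            pl = self.canonical_points[idx[left]]
            pr = self.canonical_points[idx[right]]
            mirrored = pr * np.array([-1.0, 1.0, 1.0])
            if np.max(np.abs(pl - mirrored)) > 1e-9:
                raise InvalidArgumentError(
                    f"{self.name}: pair ({left}, {right}) not mirrored about x=0")
        if self.normals is not None:
            if self.normals.shape != (n, 3):
                raise InvalidArgumentError(f"{self.name}: need one normal per label")
            norms = np.linalg.norm(self.normals, axis=1)
            if np.max(np.abs(norms - 1.0)) > 1e-9:
                raise InvalidArgumentError(f"{self.name}: normals must be unit length")

    def coplanarity_ratio(self) -> float:
        """Smallest / largest singular value of the centered coordinate matrix."""
        centered = self.canonical_points - self.canonical_points.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        return float(sv[-1] / sv[0])

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __len__(self) -> int:
        return len(self.labels)

    # -- JSON round trip (lets users substitute their own 3D model) -----
    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "labels": list(self.labels),
            "canonical_points": self.canonical_points.tolist(),
            "symmetry_pairs": [list(p) for p in self.symmetry_pairs],
            "normals": None if self.normals is None else self.normals.tolist(),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LandmarkScheme":
        d = json.loads(text)
        return cls(
            name=d["name"],
            labels=tuple(d["labels"]),
            canonical_points=np.array(d["canonical_points"], dtype=float),
            symmetry_pairs=tuple((a, b) for a, b in d.get("symmetry_pairs", [])),
            normals=None if d.get("normals") is None
            else np.array(d["normals"], dtype=float),
        )


@dataclass(frozen=True)
class MappingEntry:
    """One row of the human-face-to-cattle-head landmark correspondence."""

    aflw_label: str
    cow_label: str
    mapping_type: str  # "one-to-one" | "closest-analog"


# ----------------------------------------------------------------------
# Committed canonical head coordinates.
# Raw values before centroid-centering; unit head length along z
# (nose tip z = -0.55 to ear roots z = +0.45); "Left" labels at x < 0.
_HEAD_RAW = [
    ("Left Upper Mandible",                 (-0.30, -0.05,  0.25)),
    ("Left Eye Left Corner",                (-0.26, -0.14,  0.15)),
    ("Left Eye Right Corner",               (-0.14, -0.13,  0.05)),
    ("Right Eye Left Corner",               ( 0.14, -0.13,  0.05)),
    ("Right Eye Right Corner",              ( 0.26, -0.14,  0.15)),
    ("Right Upper Mandible",                ( 0.30, -0.05,  0.25)),
    ("Left Lower Mandible",                 (-0.26,  0.15,  0.20)),
    ("Left Eye Right Lower Corner (medial)",  (-0.14, -0.08,  0.06)),
    ("Left Eye Right Lower Corner (lateral)", (-0.24, -0.09,  0.14)),
    ("Right Eye Left Lower Corner",         ( 0.14, -0.08,  0.06)),
    ("Right Eye Right Lower Corner",        ( 0.24, -0.09,  0.14)),
    ("Right Lower Mandible",                ( 0.26,  0.15,  0.20)),
    ("Nose Left",                           (-0.10,  0.16, -0.48)),
    ("Nose Center",                         ( 0.00,  0.14, -0.55)),
    ("Nose Right",                          ( 0.10,  0.16, -0.48)),
    ("Mouth Left Corner",                   (-0.09,  0.28, -0.42)),
    ("Mouth Center",                        ( 0.00,  0.30, -0.50)),
    ("Mouth Right Corner",                  ( 0.09,  0.28, -0.42)),
    ("Left Ear Root",                       (-0.28, -0.18,  0.45)),
    ("Right Ear Root",                      ( 0.28, -0.18,  0.45)),
    ("Jaw",                                 ( 0.00,  0.34, -0.28)),
]

_HEAD_SYMMETRY = (
    ("Left Upper Mandible", "Right Upper Mandible"),
    ("Left Eye Left Corner", "Right Eye Right Corner"),
    ("Left Eye Right Corner", "Right Eye Left Corner"),
    ("Left Lower Mandible", "Right Lower Mandible"),
    ("Left Eye Right Lower Corner (medial)", "Right Eye Left Lower Corner"),
    ("Left Eye Right Lower Corner (lateral)", "Right Eye Right Lower Corner"),
    ("Nose Left", "Nose Right"),
    ("Mouth Left Corner", "Mouth Right Corner"),
    ("Left Ear Root", "Right Ear Root"),
)


@lru_cache(maxsize=1)
def head_scheme() -> LandmarkScheme:
    """The committed 21-point cattle-head landmark scheme."""
    labels = tuple(lab for lab, _ in _HEAD_RAW)
    raw = np.array([p for _, p in _HEAD_RAW], dtype=float)
    centered = raw - raw.mean(axis=0)
    # outward normals radiate from a point behind the skull so that all
    # face-surface landmarks look toward the camera at the frontal pose
    behind = np.array([0.0, 0.0, 0.8]) - raw.mean(axis=0)
    normals = centered - behind
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return LandmarkScheme("head", labels, centered, _HEAD_SYMMETRY, normals)


def _ear_patch(x: float, y: float) -> float:
    """Depth of the ear patch: elliptical paraboloid z = 2 x^2 + 0.3 (y+0.5)^2."""
    return 2.0 * x * x + 0.3 * (y + 0.5) ** 2


@lru_cache(maxsize=1)
def ear_scheme() -> LandmarkScheme:
    """The committed 13-point left-ear scheme, ordered apex to base.

    Thirteen points run down the pinna from the apex to the base along
    the medial and lateral edges of a curved patch (unit ear length
    along y).
    """
    edges = [  # (level y, half width)
        (-0.35, 0.10), (-0.20, 0.15), (-0.05, 0.18), (0.10, 0.20), (0.25, 0.19),
    ]
    labels = ["Apex"]
    raw = [(0.0, -0.5)]
    for k, (y, w) in enumerate(edges, start=1):
        labels += [f"Medial Edge {k}", f"Lateral Edge {k}"]
        raw += [(-w, y), (w, y)]
    labels += ["Base Medial", "Base Lateral"]
    raw += [(-0.12, 0.45), (0.12, 0.45)]

    pts = np.array([[x, y, _ear_patch(x, y)] for x, y in raw], dtype=float)
    # camera-facing patch normals: gradient (fx, fy, -1), normalized
    normals = np.array([[4.0 * x, 0.6 * (y + 0.5), -1.0] for x, y in raw])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    centered = pts - pts.mean(axis=0)
    return LandmarkScheme("ear", tuple(labels), centered, (), normals)


# ----------------------------------------------------------------------
# Human-face (AFLW) to cattle-head landmark correspondence.  Rows whose
# published note reads "1:1 mapping" are one-to-one; all others map to the
# closest anatomical analog.
_AFLW_ROWS = [
    ("Left Brow Left Corner",  "Left Upper Mandible",                  "closest-analog"),
    ("Left Brow Center",       "Left Eye Left Corner",                 "closest-analog"),
    ("Left Brow Right Corner", "Left Eye Right Corner",                "closest-analog"),
    ("Right Brow Left Corner", "Right Eye Left Corner",                "closest-analog"),
    ("Right Brow Center",      "Right Eye Right Corner",               "closest-analog"),
    ("Right Brow Right Corner", "Right Upper Mandible",                "closest-analog"),
    ("Left Eye Left Corner",   "Left Lower Mandible",                  "closest-analog"),
    ("Left Eye Center",        "Left Eye Right Lower Corner (medial)", "closest-analog"),
    ("Left Eye Right Corner",  "Left Eye Right Lower Corner (lateral)", "closest-analog"),
    ("Right Eye Left Corner",  "Right Eye Left Lower Corner",          "closest-analog"),
    ("Right Eye Center",       "Right Eye Right Lower Corner",         "closest-analog"),
    ("Right Eye Right Corner", "Right Lower Mandible",                 "closest-analog"),
    ("Nose Left",              "Nose Left",                            "one-to-one"),
    ("Nose Center",            "Nose Center",                          "one-to-one"),
    ("Nose Right",             "Nose Right",                           "one-to-one"),
    ("Mouth Left Corner",      "Mouth Left Corner",                    "one-to-one"),
    ("Mouth Center",           "Mouth Center",                         "one-to-one"),
    ("Mouth Right Corner",     "Mouth Right Corner",                   "one-to-one"),
    ("Left Ear Lobe",          "Left Ear Root",                        "closest-analog"),
    ("Right Ear Lobe",         "Right Ear Root",                       "closest-analog"),
    ("Chin Center",            "Jaw",                                  "one-to-one"),
]


def aflw_mapping() -> List[MappingEntry]:
    """All 21 human-to-cattle landmark correspondence entries."""
    return [MappingEntry(a, c, t) for a, c, t in _AFLW_ROWS]
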