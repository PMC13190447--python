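"""Detection-quality metrics and the occlusion-aware face-visibility ratio.

Boxes are continuous axis-aligned rectangles ``(x, y, w, h)`` with a
top-left origin and area ``w * h`` — no +1 pixel convention, keeping the
arithmetic annotation-tool agnostic.  Detection success uses a lenient
IoU threshold (0.3 by default) because face and head crops are never
perfectly aligned.  The visibility ratio of a frame is the face-box
area not covered by any occluder, normalised per camera by the maximum
observed visible area over the dataset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Box",
    "FrameBoxes",
    "DetectionCounts",
    "iou",
    "match_detections",
    "detection_metrics",
    "f1_from_precision_recall",
    "visible_face_area",
    "visibility_ratio_series",
    "interpolate_boxes",
    "load_boxes_json",
    "save_boxes_json",
]


class Box(NamedTuple):
    """Axis-aligned box: top-left (x, y), width, height — continuous pixels."""

    x: float
    y: float
    w: float
    h: float

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass
class FrameBoxes:
    """Per-frame annotation: face, occluders, detections, ground-truth boxes."""

    frame: int
    face: Box | None = None
    occluders: list[Box] = field(default_factory=list)
    detections: list[Box] = field(default_factory=list)
    ground_truth: list[Box] = field(default_factory=list)


class DetectionCounts(NamedTuple):
    tp: int
    fp: int
    fn: int

    def __add__(self, other):  # type: ignore[override]
        return DetectionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when the union is empty."""
    ix = max(0.0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
    iy = max(0.0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def match_detections(frame: FrameBoxes, threshold: float = 0.3) -> DetectionCounts:
    """Greedy one-to-one matching of detections to ground truth by IoU.

    Pairs are taken in descending IoU order; a pair with IoU >= threshold
    is a true positive, unmatched detections are false positives and
    unmatched ground-truth boxes false negatives.  With at most one
    subject per frame greedy matching is optimal.
    """
    gts, dets = frame.ground_truth, frame.detections
    pairs = sorted(
        ((iou(g, d), gi, di) for gi, g in enumerate(gts) for di, d in enumerate(dets)),
        key=lambda t: -t[0],
    )
    used_g: set[int] = set()
    used_d: set[int] = set()
    tp = 0
    for score, gi, di in pairs:
        if score < threshold:
            break
        if gi in used_g or di in used_d:
            continue
        used_g.add(gi)
        used_d.add(di)
        tp += 1
    return DetectionCounts(tp=tp, fp=len(dets) - tp, fn=len(gts) - tp)


def detection_metrics(counts: DetectionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 from matching counts.

    Each value is defined as 0 (with a log message) when its denominator
    vanishes.
    """
    tp, fp, fn = counts
    if tp + fp == 0:
        logger.info("no detections: precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.info("no ground truth: recall defined as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = f1_from_precision_recall(precision, recall)
    return precision, recall, f1


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _rect_union_area(boxes: Sequence[Box]) -> float:
    """Exact area of a union of rectangles by coordinate compression."""
    boxes = [b for b in boxes if b.w > 0 and b.h > 0]
    if not boxes:
        return 0.0
    xs = np.unique(np.concatenate([[b.x, b.x + b.w] for b in boxes]))
    ys = np.unique(np.concatenate([[b.y, b.y + b.h] for b in boxes]))
    covered = np.zeros((len(xs) - 1, len(ys) - 1), dtype=bool)
    for b in boxes:
        i0, i1 = np.searchsorted(xs, [b.x, b.x + b.w])
        j0, j1 = np.searchsorted(ys, [b.y, b.y + b.h])
        covered[i0:i1, j0:j1] = True
    cell = np.outer(np.diff(xs), np.diff(ys))
    return float(cell[covered].sum())


def visible_face_area(frame: FrameBoxes) -> float | None:
    """Face-box area not covered by the occluder union, in square pixels.

    The union of occluders clipped to the face box is computed exactly
    (coordinate compression), so overlapping occluders are never double
    counted.  Returns ``None`` when no face box is annotated; such
    frames are excluded from visibility analyses.
    """
    if frame.face is None:
        return None
    face = frame.face
    clipped: list[Box] = []
    for occ in frame.occluders:
        x0 = max(face.x, occ.x)
        y0 = max(face.y, occ.y)
        x1 = min(face.x + face.w, occ.x + occ.w)
        y1 = min(face.y + face.h, occ.y + occ.h)
        if x1 > x0 and y1 > y0:
            clipped.append(Box(x0, y0, x1 - x0, y1 - y0))
    return face.area - _rect_union_area(clipped)


def visibility_ratio_series(
    areas_by_camera: dict[str, Sequence[float | None]],
) -> dict[str, np.ndarray]:
    """Normalise visible areas to [0, 1] per camera.

    Each frame's visible face area is divided by the *per-camera*
    maximum over the whole dataset (the two views have different face
    scales, so cross-camera normalisation would be meaningless); the
    maximal frame maps to exactly 1.  ``None`` entries (no face box)
    propagate as NaN.
    """
    out: dict[str, np.ndarray] = {}
    for camera, areas in areas_by_camera.items():
        arr = np.array([np.nan if a is None else float(a) for a in areas])
        if np.all(np.isnan(arr)):
            raise ValueError(f"camera {camera!r} has no frames with a face box")
        peak = np.nanmax(arr)
        if peak <= 0:
            raise ValueError(f"camera {camera!r}: maximum visible area is not positive")
        out[camera] = arr / peak
    return out


def interpolate_boxes(frames: list[FrameBoxes], attr: str = "face") -> list[FrameBoxes]:
    """Linearly interpolate missing boxes across gaps (helper for annotation).

    Box corners are interpolated frame-index-linearly between the
    nearest annotated neighbours; leading/trailing gaps are left as is.
    """
    known = [(i, getattr(f, attr)) for i, f in enumerate(frames) if getattr(f, attr) is not None]
    if len(known) < 2:
        return frames
    idx = np.array([k for k, _ in known])
    corners = np.array([[b.x, b.y, b.w, b.h] for _, b in known])
    for i, f in enumerate(frames):
        if getattr(f, attr) is None and idx[0] <= i <= idx[-1]:
            interp = [float(np.interp(i, idx, corners[:, k])) for k in range(4)]
            setattr(f, attr, Box(*interp))
    return frames


def _box_or_none(val) -> Box | None:
    return None if val is None else Box(*map(float, val))


def load_boxes_json(path: str | Path) -> tuple[str, tuple[int, int], list[FrameBoxes]]:
    """Read a per-trial boxes file; returns (camera label, image size, frames)."""
    data = json.loads(Path(path).read_text())
    frames = [
        FrameBoxes(
            frame=int(fr["frame"]),
            face=_box_or_none(fr.get("face")),
            occluders=[Box(*map(float, b)) for b in fr.get("occluders", [])],
            detections=[Box(*map(float, b)) for b in fr.get("detections", [])],
            ground_truth=[Box(*map(float, b)) for b in fr.get("ground_truth", [])],
        )
        for fr in data["frames"]
    ]
    return data["camera"], tuple(data.get("image_size", (1280, 720))), frames


def save_boxes_json(
    path: str | Path,
    camera: str,
    frames: Iterable[FrameBoxes],
    image_size: tuple[int, int] = (1280, 720),
) -> None:
    payload = {
        "camera": camera,
        "image_size": list(image_size),
        "frames": [
            {
                "frame": f.frame,
                "face": None if f.face is None else [round(v, 4) for v in f.face],
                "occluders": [[round(v, 4) for v in b] for b in f.occluders],
                "detections": [[round(v, 4) for v in b] for b in f.detections],
                "ground_truth": [[round(v, 4) for v in b] for b in f.ground_truth],
            }
            for f in frames
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
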