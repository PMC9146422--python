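"""Shared domain types and box geometry.

Coordinates are continuous pixels with the origin at the image's top-left
corner; ``x`` grows rightward, ``y`` grows downward (the usual image
convention, and the one the MOTChallenge text formats use). A box is the
closed rectangle ``[x_min, x_max] x [y_min, y_max]`` so its width is
``x_max - x_min``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "BoundingBox",
    "Detection",
    "SequenceMeta",
    "SizeClass",
    "iou",
    "iou_matrix",
    "classify_object_size",
    "sequence_summary",
    "resolution_ratio_percent",
    "round_half_up",
]

#: Side-length thresholds (px) separating the small / medium / large object
#: classes: areas below 32x32 px^2 are "small", above 96x96 px^2 "large".
SMALL_SIDE = 32.0
LARGE_SIDE = 96.0


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero toward +inf (0.125 -> 0.13 at 2 dp).

    Python's builtin ``round`` is banker's rounding; summary statistics here
    use conventional half-up so printed values match hand calculation.
    """
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, the unit of detection."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"box coordinates must be finite, got {vals}")
        if any(v < 0 for v in vals):
            raise ValueError(f"box coordinates must be >= 0, got {vals}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box: {vals}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], dtype=float)

    @staticmethod
    def from_center(cx: float, cy: float, width: float, height: float) -> "BoundingBox":
        return BoundingBox(cx - width / 2, cy - height / 2, cx + width / 2, cy + height / 2)


@dataclass(frozen=True)
class Detection:
    """A bounding box observed in one frame, with a detector confidence."""

    frame: int
    box: BoundingBox
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame indices are 1-based, got {self.frame}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class SequenceMeta:
    """Per-sequence imaging metadata.

    ``pixel_size`` is in micrometres per pixel and ``frame_interval`` in
    minutes; both must be supplied explicitly because every physical
    migration metric depends on them.
    """

    width: int
    height: int
    n_frames: int
    frame_interval: float  # minutes
    pixel_size: float  # um / px

    def __post_init__(self) -> None:
        if min(self.width, self.height) <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_frames < 2:
            raise ValueError("a trackable sequence needs at least 2 frames")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")


@dataclass(frozen=True)
class SizeClass:
    label: str  # "small" | "medium" | "large"

    def __post_init__(self) -> None:
        if self.label not in ("small", "medium", "large"):
            raise ValueError(f"unknown size class {self.label!r}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 when equal."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two ``(n, 4)`` / ``(m, 4)`` arrays of
    ``(x_min, y_min, x_max, y_max)`` rows. Returns an ``(n, m)`` array."""
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def classify_object_size(box: BoundingBox) -> SizeClass:
    """Classify a box as small / medium / large by area.

    Thresholds follow the MOT small-object convention: area below 32x32 px^2
    is small, above 96x96 px^2 large, anything else (boundaries included)
    medium.
    """
    area = box.area
    if area < SMALL_SIDE**2:
        return SizeClass("small")
    if area > LARGE_SIDE**2:
        return SizeClass("large")
    return SizeClass("medium")


def sequence_summary(meta: SequenceMeta) -> dict[str, float]:
    """Summary statistics of a sequence: framerate, duration, frame count.

    ``frames_per_min`` is reported rounded half-up to 2 decimals (a 30-min
    interval prints as 0.03 frames/min).
    """
    if meta.frame_interval <= 0:
        raise ValueError("invalid metadata: frame_interval must be positive")
    duration_min = (meta.n_frames - 1) * meta.frame_interval
    return {
        "frames_per_min": round_half_up(1.0 / meta.frame_interval, 2),
        "duration_min": duration_min,
        "n_frames": meta.n_frames,
        "px_size": meta.pixel_size,
    }


def n_frames_for_duration(duration_min: float, interval_min: float) -> int:
    """Frame count for a stated acquisition duration, initial frame included
    (10.5 h at 30-min intervals -> 22 frames)."""
    if interval_min <= 0:
        raise ValueError("invalid metadata: frame interval must be positive")
    return int(math.floor(duration_min / interval_min)) + 1


def resolution_ratio_percent(a: float, b: float) -> float:
    """Resolution ratio 100*(a/b) rounded to the nearest 10 percent.

    With a = 1.33 um/px and b = 0.35 um/px this yields 380 (%).
    """
    if a <= 0 or b <= 0:
        raise ValueError("pixel sizes must be positive")
    return round_half_up(100.0 * a / b / 10.0) * 10.0


def detections_to_arrays(detections: Iterable[Detection]) -> tuple[np.ndarray, np.ndarray]:
    """Stack detections into ``(n, 4)`` box and ``(n,)`` confidence arrays."""
    dets = list(detections)
    if not dets:
        return np.empty((0, 4)), np.empty((0,))
    boxes = np.stack([d.box.as_array() for d in dets])
    conf = np.array([d.confidence for d in dets])
    return boxes, conf
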