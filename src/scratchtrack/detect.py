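"""Cell detection: plug-in contract, baseline blob detector, MOT det I/O.

Detectors are pluggable (Factory Method style): any callable mapping a
grayscale frame and a :class:`DetectorConfig` to a detection list can be
registered by name and used by the pipeline, so a trained model can replace
the baseline without code changes. The built-in baseline is a classical
intensity-blob detector (Gaussian smoothing, relative threshold, connected
components with watershed splitting of merged blobs, tight boxes). It exists
so the full pipeline runs and is testable end-to-end; it assumes
bright-on-dark polarity (set ``invert`` for dark cells) and rejects debris
only by the ``max_box_side`` filter, which is cruder than a learned
appearance model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .geometry import BoundingBox, Detection, iou

__all__ = [
    "DetectorConfig",
    "DetectorPlugin",
    "detect_baseline",
    "register_detector",
    "get_detector",
    "available_detectors",
    "read_detections_mot",
    "write_detections_mot",
]

DetectFn = Callable[[np.ndarray, "DetectorConfig"], list[Detection]]


@dataclass(frozen=True)
class DetectorConfig:
    smoothing_sigma: float = 2.0  # px
    intensity_threshold: float = 0.2  # relative to the frame's dynamic range
    min_box_side: float = 4.0  # px
    max_box_side: float = 40.0  # px; also the crude debris filter
    merge_iou: float = 0.6  # overlapping candidates above this are suppressed
    invert: bool = False  # True for dark cells on a bright background

    def __post_init__(self) -> None:
        if not (0.0 < self.intensity_threshold < 1.0):
            raise ValueError("intensity_threshold must be in (0, 1)")
        if not (0 < self.min_box_side < self.max_box_side):
            raise ValueError("need 0 < min_box_side < max_box_side")


@dataclass(frozen=True)
class DetectorPlugin:
    name: str
    detect: DetectFn


_REGISTRY: dict[str, DetectorPlugin] = {}


def register_detector(plugin: DetectorPlugin) -> None:
    """Register a detector plug-in under a unique name."""
    if plugin.name in _REGISTRY:
        raise ValueError(f"detector {plugin.name!r} is already registered")
    _REGISTRY[plugin.name] = plugin


def get_detector(name: str) -> DetectorPlugin:
    if name not in _REGISTRY:
        raise KeyError(f"no detector named {name!r}; available: {sorted(_REGISTRY)}")
    return _REGISTRY[name]


def available_detectors() -> list[str]:
    return sorted(_REGISTRY)


def _component_boxes(labels: np.ndarray, n_labels: int) -> list[tuple[float, float, float, float]]:
    """Tight boxes (x_min, y_min, x_max, y_max) around labelled components,
    in continuous pixel coordinates (pixel i spans [i, i+1))."""
    out = []
    for sl in ndimage.find_objects(labels, max_label=n_labels):
        if sl is None:
            out.append(None)
            continue
        ys, xs = sl
        out.append((float(xs.start), float(ys.start), float(xs.stop), float(ys.stop)))
    return out


def detect_baseline(frame_image: np.ndarray, config: DetectorConfig | None = None) -> list[Detection]:
    """Detect bright blobs in a grayscale frame.

    Pipeline: Gaussian smoothing -> threshold at ``intensity_threshold`` of
    the frame's dynamic range -> connected components; components wider than
    ``max_box_side`` are split at intensity peaks by watershed (touching
    cells), and any fragment still out of the allowed side range is dropped
    (noise specks, debris). Overlapping candidates above ``merge_iou`` keep
    the higher-confidence one. A constant image yields no detections.
    Output is sorted by (y_min, x_min) and boxes are clipped to the image.
    """
    config = config or DetectorConfig()
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("frame must be a nonempty 2-D grayscale array")
    if config.invert:
        img = img.max() - img
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return []
    norm = (img - lo) / (hi - lo)
    smoothed = ndimage.gaussian_filter(norm, config.smoothing_sigma)
    smax = smoothed.max()
    if smax <= 0:
        return []
    mask = smoothed > config.intensity_threshold * smax
    labels, n = ndimage.label(mask)

    # split merged components at local intensity maxima
    min_dist = max(2, int(config.min_box_side))
    needs_split = []
    for lab, box in enumerate(_component_boxes(labels, n), start=1):
        if box is None:
            continue
        if max(box[2] - box[0], box[3] - box[1]) > config.max_box_side:
            needs_split.append(lab)
    if needs_split:
        split_mask = np.isin(labels, needs_split)
        peaks = peak_local_max(
            smoothed, min_distance=min_dist, labels=labels, exclude_border=False
        )
        markers = np.zeros_like(labels)
        for k, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = k
        ws = watershed(-smoothed, markers, mask=split_mask)
        offset = n
        labels = np.where(split_mask, np.where(ws > 0, ws + offset, 0), labels)
        labels, n = ndimage.label(labels > 0)

    h, w = img.shape
    candidates: list[Detection] = []
    for sl in ndimage.find_objects(labels, max_label=n):
        if sl is None:
            continue
        ys, xs = sl
        x1, y1 = float(xs.start), float(ys.start)
        x2, y2 = float(min(xs.stop, w)), float(min(ys.stop, h))
        side_w, side_h = x2 - x1, y2 - y1
        if max(side_w, side_h) > config.max_box_side or min(side_w, side_h) < config.min_box_side:
            continue
        region = smoothed[ys, xs]
        conf = float(np.clip(region.max() / smax, 1e-6, 1.0))
        candidates.append(Detection(1, BoundingBox(x1, y1, x2, y2), conf))

    # non-maximum suppression on heavily overlapping candidates
    candidates.sort(key=lambda d: -d.confidence)
    kept: list[Detection] = []
    for d in candidates:
        if all(iou(d.box, k.box) <= config.merge_iou for k in kept):
            kept.append(d)
    kept.sort(key=lambda d: (d.box.y_min, d.box.x_min))
    return kept


register_detector(DetectorPlugin("baseline", detect_baseline))


# ---------------------------------------------------------------------------
# MOTChallenge detection-file I/O


def write_detections_mot(detections: Sequence[Detection], path) -> None:
    """Write detections in MOTChallenge det format:
    ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z`` with id and
    world coordinates set to -1. Output order is deterministic (frame, then
    y_min, then x_min)."""
    dets = sorted(detections, key=lambda d: (d.frame, d.box.y_min, d.box.x_min))
    with open(path, "w") as fh:
        for d in dets:
            b = d.box
            fh.write(
                f"{d.frame},-1,{b.x_min:.3f},{b.y_min:.3f},"
                f"{b.width:.3f},{b.height:.3f},{d.confidence:.6f},-1,-1,-1\n"
            )


def read_detections_mot(path) -> dict[int, list[Detection]]:
    """Read a MOTChallenge det file into detections grouped by 1-based frame.

    Malformed lines raise a parse error naming the line number; negative
    widths/heights are rejected.
    """
    out: dict[int, list[Detection]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) < 7:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 7 comma-separated fields, got {len(fields)}"
                )
            try:
                frame = int(float(fields[0]))
                left, top, width, height = (float(v) for v in fields[2:6])
                conf = float(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: unparsable number ({exc})") from None
            if width <= 0 or height <= 0:
                raise ValueError(f"{path}: line {lineno}: nonpositive box width/height")
            conf = float(np.clip(conf, 0.0, 1.0))
            det = Detection(frame, BoundingBox(left, top, left + width, top + height), conf)
            out.setdefault(frame, []).append(det)
    for f in out:
        out[f].sort(key=lambda d: (d.box.y_min, d.box.x_min))
    return out
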