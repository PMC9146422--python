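"""Image-sequence reading and track import/export.

Sequence metadata (pixel size, frame interval) is always supplied explicitly
via a sidecar JSON file or CLI flags — it is never guessed from image
headers, because every physical migration metric depends on it.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .geometry import BoundingBox, SequenceMeta
from .tracking import Track, TrackEntry

__all__ = [
    "read_image_sequence",
    "read_sequence_meta",
    "write_tracks_mot",
    "read_tracks_mot",
    "write_tracks_imagej",
    "read_tracks_imagej",
    "write_gt_mot",
]

_FRAME_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")
META_FILENAME = "sequence.json"


def read_sequence_meta(path: Path, n_frames: int, shape: tuple[int, int]) -> SequenceMeta:
    """Build SequenceMeta from a ``sequence.json`` sidecar next to the frames.

    The sidecar must contain ``pixel_size`` (um/px) and ``frame_interval``
    (minutes)."""
    base = Path(path) if Path(path).is_dir() else Path(path).parent
    candidates = [base / META_FILENAME, base.parent / META_FILENAME]
    meta_path = next((p for p in candidates if p.exists()), None)
    if meta_path is None:
        raise FileNotFoundError(
            f"no {META_FILENAME} sidecar found at {candidates[0]} (or its parent "
            "directory); pixel_size and frame_interval must be supplied explicitly"
        )
    payload = json.loads(meta_path.read_text())
    for key in ("pixel_size", "frame_interval"):
        if key not in payload:
            raise ValueError(f"{meta_path}: missing required key {key!r}")
    return SequenceMeta(
        width=shape[1],
        height=shape[0],
        n_frames=n_frames,
        frame_interval=float(payload["frame_interval"]),
        pixel_size=float(payload["pixel_size"]),
    )


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return np.asarray(img, dtype=float)


def read_image_sequence(path) -> tuple[list[np.ndarray], SequenceMeta]:
    """Read a directory of numbered frames or a multi-page TIFF.

    Frames are ordered by the numeric part of their filenames (or page
    order); a gap in the numbering is an error naming the missing frame.
    Returns grayscale float frames plus metadata from the sidecar config.
    """
    path = Path(path)
    if path.is_file():
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        frames = [_to_gray(p) for p in pages]
        meta = read_sequence_meta(path, len(frames), frames[0].shape)
        return frames, meta
    if not path.is_dir():
        raise FileNotFoundError(f"no such file or directory: {path}")
    numbered = []
    for p in sorted(path.iterdir()):
        if p.suffix.lower() not in _FRAME_EXTS:
            continue
        m = re.search(r"(\d+)", p.stem)
        if m is None:
            raise ValueError(f"frame filename without a frame number: {p.name}")
        numbered.append((int(m.group(1)), p))
    if not numbered:
        raise FileNotFoundError(f"no image frames found in {path}")
    numbered.sort()
    numbers = [n for n, _ in numbered]
    start = numbers[0]
    for k, n in enumerate(numbers):
        if n != start + k:
            raise ValueError(f"missing frame {start + k} in {path}")
    frames = []
    for _, p in numbered:
        try:
            frames.append(_to_gray(iio.imread(p)))
        except Exception as exc:
            raise OSError(f"unreadable frame {p}: {exc}") from exc
    meta = read_sequence_meta(path, len(frames), frames[0].shape)
    return frames, meta


def write_frames(frames: Sequence[np.ndarray], outdir, fmt: str = "png") -> list[Path]:
    """Write float [0, 1] frames as numbered 8-bit grayscale images."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames, start=1):
        arr = np.clip(np.asarray(frame), 0.0, 1.0)
        img = (arr * 255).astype(np.uint8)
        p = outdir / f"{i:03d}.{fmt}"
        if fmt in ("tif", "tiff"):
            tifffile.imwrite(p, img)
        else:
            iio.imwrite(p, img)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# MOTChallenge track files


def write_tracks_mot(tracks: Sequence[Track], path) -> None:
    """One line per entry, ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,
    -1,-1,-1``, sorted by frame then id. Confidence is written as 1 for real
    entries and 0 for interpolated ones so interpolation survives a round
    trip."""
    rows = []
    for t in tracks:
        for e in t.entries:
            rows.append((e.frame, t.id, e.box, 0 if e.interpolated else 1))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for frame, tid, box, conf in rows:
            fh.write(
                f"{frame},{tid},{box.x_min:.3f},{box.y_min:.3f},"
                f"{box.width:.3f},{box.height:.3f},{conf},-1,-1,-1\n"
            )


def read_tracks_mot(path) -> list[Track]:
    """Read a MOTChallenge track/gt file (id column honoured; extra columns
    beyond the seventh ignored, accommodating the gt dialect with class and
    visibility fields). Entries with confidence 0 are flagged interpolated."""
    entries: dict[int, list[TrackEntry]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 fields")
            try:
                frame = int(float(fields[0]))
                tid = int(float(fields[1]))
                left, top, width, height = (float(v) for v in fields[2:6])
                conf = float(fields[6]) if len(fields) > 6 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: unparsable number ({exc})") from None
            if width <= 0 or height <= 0:
                raise ValueError(f"{path}: line {lineno}: nonpositive box width/height")
            box = BoundingBox(left, top, left + width, top + height)
            entries.setdefault(tid, []).append(
                TrackEntry(frame, box, interpolated=(conf == 0), confidence=max(conf, 0.0))
            )
    tracks = []
    for tid in sorted(entries):
        es = sorted(entries[tid], key=lambda e: e.frame)
        tracks.append(Track(tid, es))
    return tracks


def write_gt_mot(tracks: Sequence[Track], path) -> None:
    """Write ground-truth tracks in the MOT gt dialect
    (``frame,id,bb_left,bb_top,bb_width,bb_height,conf,class,visibility``)."""
    rows = []
    for t in tracks:
        for e in t.entries:
            rows.append((e.frame, t.id, e.box))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for frame, tid, box in rows:
            fh.write(
                f"{frame},{tid},{box.x_min:.3f},{box.y_min:.3f},"
                f"{box.width:.3f},{box.height:.3f},1,1,1.0\n"
            )


# ---------------------------------------------------------------------------
# ImageJ Manual Tracking dialect


IMAGEJ_HEADER = "point\ttrack\tslice\tx\ty"


def write_tracks_imagej(tracks: Sequence[Track], path) -> None:
    """ImageJ Manual Tracking dialect: tab-separated ``point index, track
    number, frame (slice) number, x center, y center`` with 1-based indices
    and a header row. Only centers are representable in this format."""
    with open(path, "w") as fh:
        fh.write(IMAGEJ_HEADER + "\n")
        point = 1
        for t in tracks:
            for e in t.entries:
                cx, cy = e.box.center
                fh.write(f"{point}\t{t.id}\t{e.frame}\t{cx:.3f}\t{cy:.3f}\n")
                point += 1


def read_tracks_imagej(path) -> dict[int, list[tuple[int, float, float]]]:
    """Parse an ImageJ Manual Tracking export back into per-track center
    trajectories ``{track_id: [(frame, x, y), ...]}``."""
    out: dict[int, list[tuple[int, float, float]]] = {}
    with open(path) as fh:
        fh.readline()  # header row
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 tab-separated fields")
            _, tid, frame, x, y = fields
            out.setdefault(int(tid), []).append((int(frame), float(x), float(y)))
    for tid in out:
        out[tid].sort()
    return out
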