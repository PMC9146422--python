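"""Seeded scratch-assay simulator.

Emulates the study system: two confluent epithelial monolayers separated by a
horizontal wound band, imaged at 30-min intervals over 10.5 h (22 frames) at
1.33 um/px, with more than a thousand small (<32 px) cells per frame at the
default 1620x1176 px geometry. Cells within ``edge_depth`` of their wound
boundary are leading-edge cells and take wound-ward steps drawn from
``Normal(step_mean, step_sd)`` plus a lateral ``Normal(0, lateral_sd)``;
interior cells jitter isotropically. The three experiment conditions
(delayed / control / accelerated — Akt-inhibited, untreated, ROCK-inhibited
cultures) differ only in ``step_mean``.

Motion is a biased random walk, not a mechanistic monolayer model: it is
sufficient to exercise detection, association, leading-edge identification
and the migration statistics, which is what it exists for. All randomness
flows from the single ``seed``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from .geometry import BoundingBox, Detection
from .tracking import Track, TrackEntry

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PRESETS",
    "preset",
    "simulate_positions",
    "render_frames",
    "corrupt_detections",
]

#: Condition presets: wound-ward step mean in px per 30-min frame.
PRESET_STEP_MEANS = {"delayed": 3.0, "control": 8.0, "accelerated": 15.0}


@dataclass(frozen=True)
class SimConfig:
    width: int = 1620
    height: int = 1176
    n_frames: int = 22
    frame_interval: float = 30.0  # minutes
    pixel_size: float = 1.33  # um / px
    wound_rows: tuple[float, float] = (500.0, 700.0)  # (y1, y2) px
    cell_box_side: float = 20.0  # px; small-object regime (< 32 px)
    spacing: float = 28.0  # px between cell centers on the jittered grid
    grid_jitter_sd: float = 3.0  # px placement jitter of the grid
    edge_depth: float = 60.0  # px; leading-edge zone depth from the boundary
    step_mean: float = 8.0  # px / frame wound-ward (condition-dependent)
    step_sd: float = 1.5  # px / frame
    lateral_sd: float = 1.0  # px / frame
    interior_jitter_sd: float = 1.0  # px / frame, isotropic
    p_miss: float = 0.0
    fp_per_frame: int = 0
    det_jitter_sd: float = 0.0  # px corner jitter of corrupted detections
    noise_sd: float = 0.02  # intensity units on a [0, 1] scale
    debris: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        y1, y2 = self.wound_rows
        if not (0 < y1 < y2 < self.height):
            raise ValueError(f"wound_rows must satisfy 0 < y1 < y2 < height, got {self.wound_rows}")
        if self.step_mean < 0:
            raise ValueError("step_mean must be >= 0")
        if not (0 <= self.p_miss < 1):
            raise ValueError("p_miss must be in [0, 1)")
        if self.spacing <= 0 or self.cell_box_side <= 0:
            raise ValueError("spacing and cell_box_side must be positive")


def preset(name: str, **overrides) -> SimConfig:
    """Return the SimConfig for a named experiment condition."""
    if name not in PRESET_STEP_MEANS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESET_STEP_MEANS)}")
    return replace(SimConfig(), step_mean=PRESET_STEP_MEANS[name], **overrides)


PRESETS = tuple(PRESET_STEP_MEANS)


@dataclass
class GroundTruth:
    """True per-cell trajectories: one Track per cell, one entry per frame."""

    tracks: list[Track]
    config: SimConfig

    def boxes_at(self, frame: int) -> np.ndarray:
        """``(n_cells, 4)`` array of true boxes at a 1-based frame index."""
        return np.stack([t.entries[frame - 1].box.as_array() for t in self.tracks])

    def detections_at(self, frame: int) -> list[Detection]:
        return [Detection(frame, t.entries[frame - 1].box, 1.0) for t in self.tracks]


def _grid_centers(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Initial cell centers and per-cell wound direction (+1 toward +y for the
    upper monolayer, -1 for the lower).

    Rows are anchored so that the outermost row of each monolayer sits on its
    wound boundary; ``wound_rows`` is therefore the true leading-edge row
    coordinate pair that wound_analysis should recover.
    """
    y1, y2 = cfg.wound_rows
    half = cfg.cell_box_side / 2
    xs = np.arange(half, cfg.width - half + 1e-9, cfg.spacing)
    if xs.size == 0:
        raise ValueError("spacing too large: no cell column fits in the image width")
    top_rows = np.arange(y1, half - 1e-9, -cfg.spacing)
    bottom_rows = np.arange(y2, cfg.height - half + 1e-9, cfg.spacing)
    if top_rows.size == 0 and bottom_rows.size == 0:
        raise ValueError("spacing too large: no cell row fits in either monolayer")
    centers, direction = [], []
    for rows, d in ((top_rows, 1.0), (bottom_rows, -1.0)):
        for y in rows:
            for x in xs:
                centers.append((x, y))
                direction.append(d)
    c = np.array(centers, dtype=float)
    c += rng.normal(0.0, cfg.grid_jitter_sd, size=c.shape)
    return c, np.array(direction)


def simulate_positions(config: SimConfig) -> GroundTruth:
    """Simulate true cell trajectories for every frame.

    Leading-edge membership is fixed by the initial position (within
    ``edge_depth`` of the cell's own wound boundary); edge cells migrate
    wound-ward, interior cells jitter in place. Positions are clipped so the
    whole box stays inside the image. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    centers, direction = _grid_centers(config, rng)
    n = len(centers)
    y1, y2 = config.wound_rows
    boundary = np.where(direction > 0, y1, y2)
    is_edge = np.abs(centers[:, 1] - boundary) <= config.edge_depth

    half = config.cell_box_side / 2
    lo = np.array([half, half])
    hi = np.array([config.width - half, config.height - half])

    positions = np.empty((config.n_frames, n, 2))
    positions[0] = np.clip(centers, lo, hi)
    for t in range(1, config.n_frames):
        step = rng.normal(0.0, config.interior_jitter_sd, size=(n, 2))
        n_edge = int(is_edge.sum())
        step[is_edge, 0] = rng.normal(0.0, config.lateral_sd, size=n_edge)
        step[is_edge, 1] = direction[is_edge] * rng.normal(
            config.step_mean, config.step_sd, size=n_edge
        )
        positions[t] = np.clip(positions[t - 1] + step, lo, hi)

    tracks = []
    for i in range(n):
        entries = [
            TrackEntry(
                frame=t + 1,
                box=BoundingBox.from_center(
                    positions[t, i, 0], positions[t, i, 1], config.cell_box_side, config.cell_box_side
                ),
            )
            for t in range(config.n_frames)
        ]
        tracks.append(Track(id=i + 1, entries=entries))
    return GroundTruth(tracks=tracks, config=config)


def _debris_texture(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Static blotchy texture confined to the wound band."""
    img = np.zeros((cfg.height, cfg.width), dtype=np.float32)
    y1, y2 = cfg.wound_rows
    n_patches = max(3, cfg.width // 300)
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    for _ in range(n_patches):
        cx = rng.uniform(0, cfg.width)
        cy = rng.uniform(y1 + 10, y2 - 10)
        rx = rng.uniform(10, 40)
        ry = rng.uniform(5, min(20.0, (y2 - y1) / 4))
        mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 < 1
        img[mask] = np.maximum(img[mask], rng.uniform(0.2, 0.4))
    return img


def render_frames(gt: GroundTruth, config: SimConfig | None = None) -> list[np.ndarray]:
    """Render each frame as a float32 grayscale image in [0, 1].

    Each cell is a Gaussian blob (sigma = box side / 4) with a fixed per-cell
    intensity; additive Gaussian background noise; optional static debris
    inside the wound band.
    """
    cfg = config or gt.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xBEEF]))
    n = len(gt.tracks)
    amplitudes = rng.uniform(0.6, 1.0, size=n)
    sigma = cfg.cell_box_side / 4.0
    rad = int(np.ceil(3 * sigma))
    win = np.arange(-rad, rad + 1)
    debris = _debris_texture(cfg, rng) if cfg.debris else None

    frames = []
    for t in range(cfg.n_frames):
        img = np.zeros((cfg.height, cfg.width), dtype=np.float32)
        for i, track in enumerate(gt.tracks):
            cx, cy = track.entries[t].box.center
            px, py = int(round(cx)), int(round(cy))
            gx = np.exp(-((win + px - cx) ** 2) / (2 * sigma**2))
            gy = np.exp(-((win + py - cy) ** 2) / (2 * sigma**2))
            blob = amplitudes[i] * np.outer(gy, gx)
            ylo, yhi = py - rad, py + rad + 1
            xlo, xhi = px - rad, px + rad + 1
            bylo, bxlo = max(0, -ylo), max(0, -xlo)
            ylo, xlo = max(0, ylo), max(0, xlo)
            yhi, xhi = min(cfg.height, yhi), min(cfg.width, xhi)
            if yhi <= ylo or xhi <= xlo:
                continue
            sub = blob[bylo : bylo + (yhi - ylo), bxlo : bxlo + (xhi - xlo)]
            np.maximum(img[ylo:yhi, xlo:xhi], sub, out=img[ylo:yhi, xlo:xhi])
        if debris is not None:
            np.maximum(img, debris, out=img)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape).astype(np.float32)
        frames.append(np.clip(img, 0.0, 1.0))
    return frames


def corrupt_detections(
    gt: GroundTruth,
    p_miss: float | None = None,
    fp_per_frame: int | None = None,
    jitter_sd: float | None = None,
    seed: int | None = None,
) -> dict[int, list[Detection]]:
    """Derive a (possibly corrupted) detection set from the ground truth.

    Each true box is independently dropped with probability ``p_miss``;
    survivors get ``Normal(0, jitter_sd)`` noise on each corner pair;
    ``fp_per_frame`` spurious boxes are placed uniformly per frame.
    Defaults come from the GroundTruth's own config. Deterministic under
    ``seed``.
    """
    cfg = gt.config
    p_miss = cfg.p_miss if p_miss is None else p_miss
    fp_per_frame = cfg.fp_per_frame if fp_per_frame is None else fp_per_frame
    jitter_sd = cfg.det_jitter_sd if jitter_sd is None else jitter_sd
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDE7]))

    out: dict[int, list[Detection]] = {}
    side = cfg.cell_box_side
    for f in range(1, cfg.n_frames + 1):
        dets: list[Detection] = []
        for track in gt.tracks:
            if p_miss > 0 and rng.random() < p_miss:
                continue
            box = track.entries[f - 1].box
            if jitter_sd > 0:
                dx1, dy1, dx2, dy2 = rng.normal(0.0, jitter_sd, size=4)
                x1 = max(0.0, box.x_min + dx1)
                y1 = max(0.0, box.y_min + dy1)
                x2 = max(x1 + 1.0, box.x_max + dx2)
                y2 = max(y1 + 1.0, box.y_max + dy2)
                box = BoundingBox(x1, y1, x2, y2)
            dets.append(Detection(f, box, 1.0))
        for _ in range(fp_per_frame):
            cx = rng.uniform(side, cfg.width - side)
            cy = rng.uniform(side, cfg.height - side)
            dets.append(Detection(f, BoundingBox.from_center(cx, cy, side, side), 0.5))
        out[f] = dets
    return out


def config_echo(cfg: SimConfig) -> str:
    """Plain-text ``key=value`` provenance echo of a configuration."""
    lines = [f"{k}={v}" for k, v in asdict(cfg).items()]
    return "\n".join(lines) + "\n"
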