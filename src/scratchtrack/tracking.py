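"""Affinity-based tracking-by-detection for low-framerate, high-density movies.

The tracker links per-frame bounding-box detections into trajectories in two
phases:

1. **Frame-to-frame linking** (:func:`link_frames`): adjacent-frame detections
   are matched by solving a linear assignment problem on ``1 - affinity``,
   where the affinity is a convex combination of two appearance features
   (normalised cross-correlation, intensity-histogram intersection) and four
   motion features (gated centroid distance, IoU, box-size ratio, directional
   consistency). Unmatched detections seed new tracklets.
2. **Multi-stage tracklet association** (:func:`associate_tracklets`): stages
   with progressively looser temporal gates merge tracklet ends with tracklet
   starts across detection gaps (gap closing, with motion extrapolation);
   merged gaps are filled with linearly interpolated boxes flagged
   ``interpolated``. Before the final stage, tracks are *cleaved* at
   implausibly long steps so mislinked fragments can re-associate correctly.

At 30-min frame intervals a cell can move farther than the distance to its
neighbours, so motion gating plus global (rather than greedy) assignment is
what keeps identities straight; appearance carries little weight by default
because low-resolution cells all look alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import BoundingBox, Detection, iou, iou_matrix

__all__ = [
    "TrackEntry",
    "Track",
    "Tracklet",
    "AffinityConfig",
    "appearance_features",
    "motion_features",
    "combined_affinity",
    "solve_assignment",
    "link_frames",
    "associate_tracklets",
    "cleave_tracklets",
    "filter_complete_tracks",
    "track_detections",
    "group_by_frame",
]

_BIG = 1e9  # cost of an infeasible (gated-out) pair
_PATCH_SIZE = 16  # common resample size for appearance patches


@dataclass(frozen=True)
class TrackEntry:
    frame: int
    box: BoundingBox
    interpolated: bool = False
    confidence: float = 1.0


@dataclass
class Track:
    """An identity with one entry per consecutive frame of its span."""

    id: int
    entries: list[TrackEntry]

    @property
    def start_frame(self) -> int:
        return self.entries[0].frame

    @property
    def end_frame(self) -> int:
        return self.entries[-1].frame

    def centers(self) -> np.ndarray:
        return np.array([e.box.center for e in self.entries])

    def validate(self) -> None:
        frames = [e.frame for e in self.entries]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError(f"track {self.id}: frames not consecutive: {frames}")
        if all(e.interpolated for e in self.entries):
            raise ValueError(f"track {self.id}: no real (non-interpolated) entry")


#: A tracklet is just a short track; the distinction is phase, not type.
Tracklet = Track


@dataclass(frozen=True)
class AffinityConfig:
    """Weights and gates of the link affinity.

    ``w_app`` weighs (NCC, histogram intersection); ``w_mot`` weighs (gated
    distance, IoU, size ratio, directional consistency). The six weights are
    non-negative and sum to 1. ``gate_px`` is the maximum plausible centroid
    displacement per frame step (px); candidates farther than
    ``gate_px * frame_gap`` are infeasible. ``affinity_floor`` is the minimum
    combined affinity for a link to survive. ``cleave_factor`` is the multiple
    of a track's median step length beyond which a step is cut.
    """

    w_app: tuple[float, float] = (0.15, 0.15)
    w_mot: tuple[float, float, float, float] = (0.30, 0.20, 0.10, 0.10)
    gate_px: float = 25.0
    max_gap_frames: int = 3
    affinity_floor: float = 0.1
    cleave_factor: float = 4.0

    def __post_init__(self) -> None:
        w = (*self.w_app, *self.w_mot)
        if any(x < 0 for x in w):
            raise ValueError("affinity weights must be >= 0")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"affinity weights must sum to 1, got {sum(w)}")
        if self.gate_px <= 0:
            raise ValueError("gate_px must be positive")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if not (0 <= self.affinity_floor < 1):
            raise ValueError("affinity_floor must be in [0, 1)")

    def motion_only_weights(self) -> np.ndarray:
        """Motion weights renormalised to sum to 1, for image-free runs."""
        w = np.array(self.w_mot, dtype=float)
        s = w.sum()
        if s == 0:
            raise ValueError("cannot track without images when all motion weights are 0")
        return w / s


# ---------------------------------------------------------------------------
# features


def _resample_patch(patch: np.ndarray, size: int = _PATCH_SIZE) -> np.ndarray:
    """Resample a 2-D patch to ``size x size`` by nearest-index sampling and
    normalise intensities to [0, 1] if 8-bit."""
    p = np.asarray(patch, dtype=float)
    if p.ndim != 2 or p.size == 0:
        raise ValueError("patch must be a nonempty 2-D array")
    if p.max() > 1.0:
        p = p / 255.0
    rows = np.clip((np.arange(size) + 0.5) * p.shape[0] / size, 0, p.shape[0] - 1).astype(int)
    cols = np.clip((np.arange(size) + 0.5) * p.shape[1] / size, 0, p.shape[1] - 1).astype(int)
    return p[np.ix_(rows, cols)]


def appearance_features(patch_a: np.ndarray, patch_b: np.ndarray) -> tuple[float, float]:
    """Two appearance affinities in [0, 1] between image patches.

    Feature 1 is the normalised cross-correlation mapped from [-1, 1] to
    [0, 1]; feature 2 is the intensity-histogram intersection. Both are 1 for
    identical patches. Zero-variance (flat) patches cannot be correlated:
    two equal flat patches score 1, a flat vs a structured patch scores the
    neutral 0.5.
    """
    a = _resample_patch(patch_a)
    b = _resample_patch(patch_b)
    sa, sb = a.std(), b.std()
    if sa == 0 and sb == 0:
        ncc_score = 1.0 if abs(a.mean() - b.mean()) < 1e-12 else 0.0
    elif sa == 0 or sb == 0:
        ncc_score = 0.5
    else:
        ncc = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        ncc_score = (np.clip(ncc, -1.0, 1.0) + 1.0) / 2.0
    ha, _ = np.histogram(a, bins=16, range=(0.0, 1.0))
    hb, _ = np.histogram(b, bins=16, range=(0.0, 1.0))
    hist_score = float(np.minimum(ha, hb).sum() / a.size)
    return float(ncc_score), hist_score


def _velocity(track: Track) -> np.ndarray | None:
    """Per-frame velocity from the last two entries, or None for singletons."""
    if len(track.entries) < 2:
        return None
    c2 = np.array(track.entries[-1].box.center)
    c1 = np.array(track.entries[-2].box.center)
    dt = track.entries[-1].frame - track.entries[-2].frame
    return (c2 - c1) / dt


def _cos_score(v: np.ndarray | None, step: np.ndarray) -> float:
    """Directional consistency (1 + cos)/2; 0.5 when direction is undefined."""
    if v is None:
        return 0.5
    nv, ns = np.linalg.norm(v), np.linalg.norm(step)
    if nv < 1e-12 or ns < 1e-12:
        return 0.5
    return float((1.0 + np.dot(v, step) / (nv * ns)) / 2.0)


def motion_features(
    tracklet_tail: Track, candidate: Detection, gate_px: float
) -> tuple[float, float, float, float]:
    """Four motion affinities in [0, 1] between a tracklet's tail and a
    candidate detection in a later frame.

    f1: centroid distance gated by ``gate_px * frame_gap``; f2: IoU of the
    last box and the candidate box; f3: area ratio min/max; f4: directional
    consistency of the proposed step with the recent velocity (0.5 when the
    tracklet has a single entry).
    """
    last = tracklet_tail.entries[-1]
    gap = candidate.frame - last.frame
    if gap <= 0:
        raise ValueError(
            f"candidate frame {candidate.frame} is not after tracklet end {last.frame}"
        )
    c_last = np.array(last.box.center)
    c_cand = np.array(candidate.box.center)
    dist = float(np.linalg.norm(c_cand - c_last))
    f1 = 1.0 - min(dist / (gate_px * gap), 1.0)
    f2 = iou(last.box, candidate.box)
    a1, a2 = last.box.area, candidate.box.area
    f3 = min(a1, a2) / max(a1, a2)
    f4 = _cos_score(_velocity(tracklet_tail), c_cand - c_last)
    return f1, f2, f3, f4


def combined_affinity(
    app: Sequence[float], mot: Sequence[float], config: AffinityConfig
) -> float:
    """Convex weighted sum of the six feature scores; in [0, 1] and monotone
    nondecreasing in every score."""
    scores = np.array([*app, *mot], dtype=float)
    if scores.shape != (6,):
        raise ValueError("expected two appearance and four motion scores")
    w = np.array([*config.w_app, *config.w_mot])
    return float(np.dot(w, scores))


# ---------------------------------------------------------------------------
# assignment


def solve_assignment(
    cost_matrix: np.ndarray, gate_cost: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost one-to-one matching with gating.

    Returns ``(matches, unmatched_rows, unmatched_cols)``. The matching
    minimises total cost over all one-to-one matchings (Hungarian / linear
    assignment); matched pairs whose cost exceeds ``gate_cost`` are severed
    into the unmatched sets. An empty matrix yields an empty matching.
    """
    cost = np.atleast_2d(np.asarray(cost_matrix, dtype=float))
    if cost.size == 0:
        n_rows = cost.shape[0] if cost.ndim == 2 else 0
        n_cols = cost.shape[1] if cost.ndim == 2 else 0
        return [], list(range(n_rows)), list(range(n_cols))
    if not np.isfinite(cost).all():
        raise ValueError("cost matrix must be finite (use a large cost for infeasible pairs)")
    rows, cols = linear_sum_assignment(cost)
    matches, un_rows, un_cols = [], set(range(cost.shape[0])), set(range(cost.shape[1]))
    for r, c in zip(rows, cols):
        if cost[r, c] > gate_cost:
            continue
        matches.append((int(r), int(c)))
        un_rows.discard(int(r))
        un_cols.discard(int(c))
    return matches, sorted(un_rows), sorted(un_cols)


# ---------------------------------------------------------------------------
# stage 1: frame-to-frame linking


def group_by_frame(detections: Iterable[Detection]) -> dict[int, list[Detection]]:
    """Group a flat detection list by 1-based frame index, sorted
    deterministically (y_min then x_min within each frame)."""
    out: dict[int, list[Detection]] = {}
    for d in detections:
        out.setdefault(d.frame, []).append(d)
    for f in out:
        out[f].sort(key=lambda d: (d.box.y_min, d.box.x_min))
    return out


def _extract_patch(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    h, w = image.shape
    x1 = int(np.clip(np.floor(box.x_min), 0, w - 1))
    x2 = int(np.clip(np.ceil(box.x_max), x1 + 1, w))
    y1 = int(np.clip(np.floor(box.y_min), 0, h - 1))
    y2 = int(np.clip(np.ceil(box.y_max), y1 + 1, h))
    return image[y1:y2, x1:x2]


def _pair_costs(
    tail_tracks: Sequence[Track],
    candidates: Sequence[Detection],
    gaps: np.ndarray,
    config: AffinityConfig,
    images: Sequence[np.ndarray] | None,
    extrapolate: bool,
) -> np.ndarray:
    """Cost matrix ``1 - affinity`` between tracklet tails and candidate
    detections; infeasible pairs get a large cost.

    ``gaps[i, j]`` is the frame gap for pair (i, j). With ``extrapolate`` the
    tail position is advanced by its recent velocity times the gap before the
    distance/IoU features are computed (used in gap closing).
    """
    n_r, n_c = len(tail_tracks), len(candidates)
    if n_r == 0 or n_c == 0:
        return np.zeros((n_r, n_c))
    tails = [t.entries[-1] for t in tail_tracks]
    last_boxes = np.stack([e.box.as_array() for e in tails])
    last_centers = np.array([e.box.center for e in tails])
    vels = [_velocity(t) for t in tail_tracks]
    cand_boxes = np.stack([d.box.as_array() for d in candidates])
    cand_centers = 0.5 * (cand_boxes[:, :2] + cand_boxes[:, 2:])

    if extrapolate:
        vel_arr = np.array([v if v is not None else (0.0, 0.0) for v in vels])
        shift = vel_arr[:, None, :] * gaps[:, :, None]  # (R, C, 2)
        pred_centers = last_centers[:, None, :] + shift
        pred_boxes = last_boxes[:, None, :] + np.concatenate([shift, shift], axis=2)
        dist = np.linalg.norm(pred_centers - cand_centers[None, :, :], axis=2)
        ix = np.minimum(pred_boxes[:, :, 2], cand_boxes[None, :, 2]) - np.maximum(
            pred_boxes[:, :, 0], cand_boxes[None, :, 0]
        )
        iy = np.minimum(pred_boxes[:, :, 3], cand_boxes[None, :, 3]) - np.maximum(
            pred_boxes[:, :, 1], cand_boxes[None, :, 1]
        )
        inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
        area_r = (last_boxes[:, 2] - last_boxes[:, 0]) * (last_boxes[:, 3] - last_boxes[:, 1])
        area_c = (cand_boxes[:, 2] - cand_boxes[:, 0]) * (cand_boxes[:, 3] - cand_boxes[:, 1])
        f2 = inter / (area_r[:, None] + area_c[None, :] - inter)
    else:
        dist = np.linalg.norm(last_centers[:, None, :] - cand_centers[None, :, :], axis=2)
        f2 = iou_matrix(last_boxes, cand_boxes)
        area_r = (last_boxes[:, 2] - last_boxes[:, 0]) * (last_boxes[:, 3] - last_boxes[:, 1])
        area_c = (cand_boxes[:, 2] - cand_boxes[:, 0]) * (cand_boxes[:, 3] - cand_boxes[:, 1])

    gate = config.gate_px * gaps
    feasible = (gaps >= 1) & (dist <= gate)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(gaps >= 1, 1.0 - np.minimum(dist / np.maximum(gate, 1e-12), 1.0), 0.0)
    f3 = np.minimum(area_r[:, None], area_c[None, :]) / np.maximum(
        area_r[:, None], area_c[None, :]
    )
    # directional consistency of the raw step with the tail velocity
    steps = cand_centers[None, :, :] - last_centers[:, None, :]
    f4 = np.full((n_r, n_c), 0.5)
    step_norm = np.linalg.norm(steps, axis=2)
    for i, v in enumerate(vels):
        if v is None:
            continue
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            continue
        ok = step_norm[i] >= 1e-12
        f4[i, ok] = (1.0 + steps[i, ok] @ v / (nv * step_norm[i, ok])) / 2.0

    if images is None:
        w = config.motion_only_weights()
        affinity = w[0] * f1 + w[1] * f2 + w[2] * f3 + w[3] * f4
    else:
        affinity = (
            config.w_mot[0] * f1 + config.w_mot[1] * f2 + config.w_mot[2] * f3 + config.w_mot[3] * f4
        )
        wa = sum(config.w_app)
        if wa > 0:
            app = np.zeros((n_r, n_c))
            for i, j in zip(*np.nonzero(feasible)):
                tail = tails[i]
                img_a = images[tail.frame - 1]
                img_b = images[candidates[j].frame - 1]
                s1, s2 = appearance_features(
                    _extract_patch(img_a, tail.box), _extract_patch(img_b, candidates[j].box)
                )
                app[i, j] = config.w_app[0] * s1 + config.w_app[1] * s2
            affinity = affinity + app

    cost = 1.0 - affinity
    cost[~feasible] = _BIG
    return cost


def link_frames(
    detections_by_frame: Mapping[int, Sequence[Detection]] | Iterable[Detection],
    config: AffinityConfig | None = None,
    images: Sequence[np.ndarray] | None = None,
) -> list[Track]:
    """Build stage-1 tracklets by per-adjacent-frame assignment.

    Costs are ``1 - combined_affinity`` with gate ``1 - affinity_floor``;
    candidates beyond ``gate_px`` are infeasible. Unmatched detections start
    new tracklets; every detection belongs to exactly one tracklet.
    """
    config = config or AffinityConfig()
    if not isinstance(detections_by_frame, Mapping):
        detections_by_frame = group_by_frame(detections_by_frame)
    if not detections_by_frame:
        return []
    n_frames = max(detections_by_frame)
    gate_cost = 1.0 - config.affinity_floor

    tracks: list[Track] = []
    next_id = 1
    active: list[Track] = []
    for d in sorted(
        detections_by_frame.get(1, []), key=lambda d: (d.box.y_min, d.box.x_min)
    ):
        t = Track(next_id, [TrackEntry(1, d.box, confidence=d.confidence)])
        next_id += 1
        tracks.append(t)
        active.append(t)

    for f in range(2, n_frames + 1):
        cands = sorted(
            detections_by_frame.get(f, []), key=lambda d: (d.box.y_min, d.box.x_min)
        )
        rows = [t for t in active if t.end_frame == f - 1]
        gaps = np.ones((len(rows), len(cands)))
        cost = _pair_costs(rows, cands, gaps, config, images, extrapolate=False)
        matches, _, un_cols = solve_assignment(cost, gate_cost) if len(rows) and len(cands) else (
            [],
            [],
            list(range(len(cands))),
        )
        matched_rows = set()
        for r, c in matches:
            rows[r].entries.append(TrackEntry(f, cands[c].box, confidence=cands[c].confidence))
            matched_rows.add(r)
        new_active = [t for t in active if t.end_frame >= f]
        for c in un_cols:
            t = Track(next_id, [TrackEntry(f, cands[c].box, confidence=cands[c].confidence)])
            next_id += 1
            tracks.append(t)
            new_active.append(t)
        active = new_active
    return tracks


# ---------------------------------------------------------------------------
# stage 2: multi-stage association with gap closing, cleaving


def _interpolate_gap(a: TrackEntry, b: TrackEntry) -> list[TrackEntry]:
    """Linearly interpolated entries strictly between ``a`` and ``b``,
    flagged interpolated with confidence 0."""
    out = []
    gap = b.frame - a.frame
    box_a, box_b = a.box.as_array(), b.box.as_array()
    for k in range(1, gap):
        w = k / gap
        x1, y1, x2, y2 = (1 - w) * box_a + w * box_b
        out.append(TrackEntry(a.frame + k, BoundingBox(x1, y1, x2, y2), True, 0.0))
    return out


def _merge(left: Track, right: Track) -> Track:
    entries = list(left.entries)
    entries.extend(_interpolate_gap(left.entries[-1], right.entries[0]))
    entries.extend(right.entries)
    return Track(left.id, entries)


def _associate_stage(
    tracks: list[Track],
    gap_limit: int,
    config: AffinityConfig,
    images: Sequence[np.ndarray] | None,
) -> list[Track]:
    """One association stage: merge track ends to track starts across gaps of
    at most ``gap_limit`` frames, solved as one global assignment."""
    n = len(tracks)
    if n < 2:
        return tracks
    starts = np.array([t.start_frame for t in tracks])
    ends = np.array([t.end_frame for t in tracks])
    gaps = starts[None, :] - ends[:, None]  # (left, right)
    valid = (gaps >= 1) & (gaps <= gap_limit)
    np.fill_diagonal(valid, False)
    if not valid.any():
        return tracks
    head_dets = [Detection(t.start_frame, t.entries[0].box, 1.0) for t in tracks]
    cost = _pair_costs(tracks, head_dets, gaps.astype(float), config, images, extrapolate=True)
    cost[~valid] = _BIG
    matches, _, _ = solve_assignment(cost, 1.0 - config.affinity_floor)

    succ = {r: c for r, c in matches}
    merged_into: set[int] = set(succ.values())
    out: list[Track] = []
    for i in range(n):
        if i in merged_into:
            continue
        chain = tracks[i]
        j = i
        while j in succ:
            j = succ[j]
            chain = _merge(chain, tracks[j])
        out.append(chain)
    return out


def cleave_tracklets(tracks: list[Track], config: AffinityConfig | None = None) -> list[Track]:
    """Cut tracks at implausibly long steps (suspected identity switches).

    A step longer than ``cleave_factor`` times the track's median
    real-to-real (non-interpolated) step length is severed; fragments keep
    the track invariants (boundary interpolated entries are stripped).
    Tracks with fewer than 3 entries are never cleaved.
    """
    config = config or AffinityConfig()
    out: list[Track] = []
    next_id = 1
    for track in tracks:
        fragments = [track.entries]
        if len(track.entries) >= 3:
            centers = track.centers()
            steps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
            real = np.array(
                [
                    not (track.entries[k].interpolated or track.entries[k + 1].interpolated)
                    for k in range(len(steps))
                ]
            )
            if real.any():
                med = float(np.median(steps[real]))
                cut_after = np.nonzero(steps > config.cleave_factor * med)[0]
                if cut_after.size:
                    fragments = []
                    prev = 0
                    for k in cut_after:
                        fragments.append(track.entries[prev : k + 1])
                        prev = k + 1
                    fragments.append(track.entries[prev:])
        for frag in fragments:
            while frag and frag[0].interpolated:
                frag = frag[1:]
            while frag and frag[-1].interpolated:
                frag = frag[:-1]
            if frag and not all(e.interpolated for e in frag):
                out.append(Track(next_id, list(frag)))
                next_id += 1
    return out


def associate_tracklets(
    tracklets: list[Track],
    config: AffinityConfig | None = None,
    images: Sequence[np.ndarray] | None = None,
) -> list[Track]:
    """Multi-stage tracklet association with gap closing.

    Stage ``s`` allows temporal gaps up to ``s`` frames (spatial gate
    ``gate_px * gap``), so easy continuations are resolved before risky
    long-gap merges; cleaving runs before the final stage so mislinked
    fragments can re-associate. Returns gap-closed tracks with fresh ids.
    """
    config = config or AffinityConfig()
    tracks = [Track(t.id, list(t.entries)) for t in tracklets]
    stages = list(range(1, config.max_gap_frames + 1))
    for k, s in enumerate(stages):
        if k == len(stages) - 1:
            tracks = cleave_tracklets(tracks, config)
        tracks = _associate_stage(tracks, s, config, images)
    if not stages:
        tracks = cleave_tracklets(tracks, config)
    tracks.sort(key=lambda t: (t.start_frame, t.entries[0].box.y_min, t.entries[0].box.x_min))
    for i, t in enumerate(tracks):
        t.id = i + 1
    return tracks


def filter_complete_tracks(tracks: Sequence[Track], n_frames: int) -> list[Track]:
    """Keep exactly the tracks spanning frames ``1..n_frames`` with no missing
    frame; interpolated entries count as present."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    out = []
    for t in tracks:
        if t.start_frame == 1 and t.end_frame == n_frames and len(t.entries) == n_frames:
            out.append(t)
    return out


def track_detections(
    detections_by_frame: Mapping[int, Sequence[Detection]] | Iterable[Detection],
    config: AffinityConfig | None = None,
    images: Sequence[np.ndarray] | None = None,
) -> list[Track]:
    """Full tracking pipeline: frame-to-frame linking followed by multi-stage
    association with cleaving and gap closing."""
    config = config or AffinityConfig()
    tracklets = link_frames(detections_by_frame, config, images)
    return associate_tracklets(tracklets, config, images)
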