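"""Ground-truth-based tracking evaluation (CLEAR-MOT style).

Per frame, ground-truth and hypothesis boxes are matched one-to-one at an IoU
threshold, keeping the previous frame's correspondences whenever they remain
valid (the CLEAR continuity rule); remaining boxes are matched to maximise
total IoU. False positives, misses and identity switches accumulate into

    MOTA = 1 - (FP + FN + IDSW) / n_gt

plus two track-level recovery fractions used for tracker acceptance against
the simulator's perfect ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import iou_matrix
from .tracking import Track

__all__ = ["EvalResult", "match_frame", "clear_mot", "detection_complete_recovery"]


@dataclass(frozen=True)
class EvalResult:
    n_gt: int  # ground-truth object-frames
    fp: int
    fn: int
    idsw: int
    mota: float
    complete_track_recovery: float  # GT tracks matched to one hyp id in every frame

    def __post_init__(self) -> None:
        expected = 1.0 - (self.fp + self.fn + self.idsw) / self.n_gt
        if abs(self.mota - expected) > 1e-9:
            raise ValueError("inconsistent MOTA")


def match_frame(
    gt_boxes: np.ndarray,
    hyp_boxes: np.ndarray,
    iou_threshold: float = 0.5,
    prior: dict[int, int] | None = None,
) -> list[tuple[int, int]]:
    """One-to-one matching of one frame's boxes maximising total IoU among
    pairs with IoU >= threshold.

    ``prior`` maps gt row index -> hyp column index from the previous frame;
    such pairs are kept first whenever still above threshold (continuity
    rule). Inputs are ``(n, 4)`` arrays of ``x_min, y_min, x_max, y_max``.
    """
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    hyp_boxes = np.asarray(hyp_boxes, dtype=float).reshape(-1, 4)
    if gt_boxes.shape[0] == 0 or hyp_boxes.shape[0] == 0:
        return []
    ious = iou_matrix(gt_boxes, hyp_boxes)
    matches: list[tuple[int, int]] = []
    used_g, used_h = set(), set()
    if prior:
        for g, h in prior.items():
            if g < ious.shape[0] and h < ious.shape[1] and ious[g, h] >= iou_threshold:
                matches.append((g, h))
                used_g.add(g)
                used_h.add(h)
    rem_g = [g for g in range(ious.shape[0]) if g not in used_g]
    rem_h = [h for h in range(ious.shape[1]) if h not in used_h]
    if rem_g and rem_h:
        sub = ious[np.ix_(rem_g, rem_h)]
        rows, cols = linear_sum_assignment(-sub)
        for r, c in zip(rows, cols):
            if sub[r, c] >= iou_threshold:
                matches.append((rem_g[r], rem_h[c]))
    return sorted(matches)


def _by_frame(tracks: Sequence[Track]) -> dict[int, list[tuple[int, np.ndarray]]]:
    out: dict[int, list[tuple[int, np.ndarray]]] = {}
    for t in tracks:
        for e in t.entries:
            out.setdefault(e.frame, []).append((t.id, e.box.as_array()))
    return out


def clear_mot(
    gt_tracks: Sequence[Track],
    hyp_tracks: Sequence[Track],
    iou_threshold: float = 0.5,
) -> EvalResult:
    """Accumulate CLEAR-MOT counts over all frames.

    Interpolated hypothesis entries count as ordinary boxes (a gap-closed
    track is credited for bridging a miss only if its interpolation is
    accurate enough to match). An identity switch is counted when a GT track
    changes its matched hypothesis identity between its matched frames.
    """
    gt_frames = _by_frame(gt_tracks)
    hyp_frames = _by_frame(hyp_tracks)
    if not gt_frames:
        raise ValueError("MOTA is undefined with empty ground truth")
    frames = sorted(set(gt_frames) | set(hyp_frames))
    n_gt = fp = fn = idsw = 0
    last_hyp_for_gt: dict[int, int] = {}  # gt id -> hyp id
    # per-GT-track matched-every-frame bookkeeping
    matched_frames: dict[int, int] = {t.id: 0 for t in gt_tracks}
    hyp_ids_for_gt: dict[int, set[int]] = {t.id: set() for t in gt_tracks}

    prev_pairs: dict[int, int] = {}  # gt id -> hyp id matched in previous frame
    for f in frames:
        gts = gt_frames.get(f, [])
        hyps = hyp_frames.get(f, [])
        n_gt += len(gts)
        gt_ids = [g for g, _ in gts]
        hyp_ids = [h for h, _ in hyps]
        prior = {}
        for gi, gid in enumerate(gt_ids):
            hid = prev_pairs.get(gid)
            if hid is not None and hid in hyp_ids:
                prior[gi] = hyp_ids.index(hid)
        gt_arr = np.stack([b for _, b in gts]) if gts else np.empty((0, 4))
        hyp_arr = np.stack([b for _, b in hyps]) if hyps else np.empty((0, 4))
        pairs = match_frame(gt_arr, hyp_arr, iou_threshold, prior)
        fn += len(gts) - len(pairs)
        fp += len(hyps) - len(pairs)
        new_pairs: dict[int, int] = {}
        for g, h in pairs:
            gid, hid = gt_ids[g], hyp_ids[h]
            prev_hid = last_hyp_for_gt.get(gid)
            if prev_hid is not None and prev_hid != hid:
                idsw += 1
            last_hyp_for_gt[gid] = hid
            new_pairs[gid] = hid
            matched_frames[gid] = matched_frames.get(gid, 0) + 1
            hyp_ids_for_gt.setdefault(gid, set()).add(hid)
        prev_pairs = new_pairs

    complete = 0
    for t in gt_tracks:
        if matched_frames.get(t.id, 0) == len(t.entries) and len(hyp_ids_for_gt.get(t.id, ())) == 1:
            complete += 1
    return EvalResult(
        n_gt=n_gt,
        fp=fp,
        fn=fn,
        idsw=idsw,
        mota=1.0 - (fp + fn + idsw) / n_gt,
        complete_track_recovery=complete / len(gt_tracks),
    )


def detection_complete_recovery(
    gt_tracks: Sequence[Track],
    hyp_tracks: Sequence[Track],
    iou_threshold: float = 0.5,
) -> float:
    """Fraction of GT tracks recovered end-to-end over their detectable span.

    A GT track counts as recovered when every frame in which it was actually
    detected (i.e. every non-interpolated hypothesis entry matching it) falls
    in one single hypothesis track, that track contains no other cell's
    detections, and no detected frame of the GT track is left out. Interior
    detector misses bridged by interpolation do not break recovery; a
    fragmented or identity-mixed trajectory does.
    """
    gt_frames = _by_frame(gt_tracks)
    # map every real hypothesis entry to the GT id it overlaps best
    owner: dict[int, dict[int, set[int]]] = {}  # hyp id -> gt id -> frames
    real_frames: dict[int, dict[int, int]] = {}  # gt id -> frame -> hyp id
    for t in hyp_tracks:
        for e in t.entries:
            if e.interpolated:
                continue
            gts = gt_frames.get(e.frame, [])
            if not gts:
                continue
            gt_arr = np.stack([b for _, b in gts])
            ious = iou_matrix(e.box.as_array()[None, :], gt_arr)[0]
            best = int(np.argmax(ious))
            if ious[best] < iou_threshold:
                continue
            gid = gts[best][0]
            owner.setdefault(t.id, {}).setdefault(gid, set()).add(e.frame)
            real_frames.setdefault(gid, {})[e.frame] = t.id

    recovered = 0
    for t in gt_tracks:
        per_frame = real_frames.get(t.id)
        if not per_frame:
            continue
        hyp_ids = set(per_frame.values())
        if len(hyp_ids) != 1:
            continue  # fragmented across hypothesis identities
        hid = next(iter(hyp_ids))
        if len(owner.get(hid, {})) != 1:
            continue  # hypothesis mixes several cells
        recovered += 1
    return recovered / len(gt_tracks)
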