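"""End-to-end analysis of one wound-repair experiment.

Chains the stages: detections -> tracking -> complete-track filtering ->
leading-edge identification (frame 1) -> leading-edge track selection and
sampling -> migration metrics. The result object carries everything the
report and the group statistics need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import Detection, SequenceMeta
from .metrics import METRIC_NAMES, MigrationMetrics, compute_metrics
from .tracking import AffinityConfig, Track, filter_complete_tracks, track_detections
from .wound import (
    EligibleTrack,
    LeadingEdges,
    WoundClosedError,
    identify_leading_edges,
    row_density_profile,
    sample_tracks,
    select_leading_edge_tracks,
)

__all__ = ["ExperimentResult", "analyze_experiment", "metrics_table"]


@dataclass
class ExperimentResult:
    condition: str
    meta: SequenceMeta
    tracks: list[Track]
    complete_tracks: list[Track]
    edges: LeadingEdges | None  # None when the wound is closed in frame 1
    eligible: list[EligibleTrack]
    sampled: list[EligibleTrack]
    metrics: list[MigrationMetrics]
    detections_per_frame: dict[int, int] = field(default_factory=dict)
    seed: int = 0

    @property
    def wound_closed(self) -> bool:
        return self.edges is None


def analyze_experiment(
    detections_by_frame: Mapping[int, Sequence[Detection]],
    meta: SequenceMeta,
    condition: str = "control",
    affinity: AffinityConfig | None = None,
    images: Sequence[np.ndarray] | None = None,
    bin_height: float = 10.0,
    smooth_window: int = 5,
    alpha: float = 0.25,
    margin: float = 50.0,
    n_sample: int = 20,
    seed: int = 0,
) -> ExperimentResult:
    """Run the full single-experiment pipeline on a detection set."""
    affinity = affinity or AffinityConfig()
    tracks = track_detections(detections_by_frame, affinity, images)
    complete = filter_complete_tracks(tracks, meta.n_frames)

    frame1 = list(detections_by_frame.get(1, []))
    profile = row_density_profile(frame1, meta, bin_height, smooth_window)
    try:
        edges = identify_leading_edges(profile, alpha)
    except WoundClosedError as exc:
        warnings.warn(f"condition {condition!r}: {exc}", stacklevel=2)
        edges = None
    eligible: list[EligibleTrack] = []
    sampled: list[EligibleTrack] = []
    metrics: list[MigrationMetrics] = []
    if edges is not None:
        eligible = select_leading_edge_tracks(complete, edges, margin)
        sampled = sample_tracks(eligible, n_sample, seed) if eligible else []
        metrics = [compute_metrics(et.track, meta, et.wound_direction) for et in sampled]
    counts = {f: len(detections_by_frame.get(f, [])) for f in range(1, meta.n_frames + 1)}
    return ExperimentResult(
        condition=condition,
        meta=meta,
        tracks=tracks,
        complete_tracks=complete,
        edges=edges,
        eligible=eligible,
        sampled=sampled,
        metrics=metrics,
        detections_per_frame=counts,
        seed=seed,
    )


def metrics_table(result: ExperimentResult) -> pd.DataFrame:
    """One row per sampled track: id, condition, wound direction, six metrics."""
    rows = []
    for et, m in zip(result.sampled, result.metrics):
        row = {
            "track_id": et.track.id,
            "condition": result.condition,
            "wound_direction": "+y" if et.wound_direction > 0 else "-y",
        }
        row.update({name: m.value(name) for name in METRIC_NAMES})
        row["degenerate"] = m.degenerate
        rows.append(row)
    return pd.DataFrame(rows)
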