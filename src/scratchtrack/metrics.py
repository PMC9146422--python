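"""Per-track migration metrics and condition comparisons.

The six wound-repair metrics follow the conventions of standard chemotaxis
analysis tools. For a track with box centers :math:`c_1..c_T` (px), pixel
size :math:`s` (um/px) and frame interval :math:`\\Delta t` (min):

- Euclidean distance: :math:`s\\,\\lVert c_T - c_1\\rVert` (um)
- accumulated distance: :math:`s \\sum_t \\lVert c_{t+1}-c_t \\rVert` (um)
- velocity: accumulated distance / elapsed hours (mean speed, um/h)
- directionality: Euclidean / accumulated, in [0, 1]
- Y-forward migration index: signed wound-ward net y displacement /
  accumulated distance, in [-1, 1]; positive toward the wound for both
  top- and bottom-edge cells, so conditions are comparable across edges
- end-point angle: direction of :math:`c_T - c_1` in degrees, measured
  counterclockwise from +x in a wound-ward frame where the wound direction
  maps to +90 degrees.

Conditions are compared per metric with two-sample Wilcoxon-Mann-Whitney
tests (exact permutation enumeration for small samples, tie-corrected normal
approximation otherwise), with no multiplicity adjustment by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .geometry import SequenceMeta
from .tracking import Track

__all__ = [
    "MigrationMetrics",
    "GroupComparison",
    "METRIC_NAMES",
    "compute_metrics",
    "mww_test",
    "compare_groups",
]

METRIC_NAMES = (
    "euclidean_distance",
    "accumulated_distance",
    "velocity",
    "directionality",
    "y_fmi",
    "end_point_angle",
)


@dataclass(frozen=True)
class MigrationMetrics:
    euclidean_distance: float  # um
    accumulated_distance: float  # um
    velocity: float  # um/h
    directionality: float  # unitless in [0, 1]
    y_fmi: float  # unitless in [-1, 1]
    end_point_angle: float  # degrees in [0, 360)
    degenerate: bool = False  # True when the track never moved (angle undefined)

    def value(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    significant: bool  # p < alpha


def compute_metrics(
    track: Track, meta: SequenceMeta, wound_direction: int
) -> MigrationMetrics:
    """Compute the six migration metrics for one track.

    ``wound_direction`` is +1 when the wound lies toward +y (image down) from
    the cell's monolayer and -1 otherwise. Interpolated entries are part of
    the trajectory. A stationary track reports zero distances, directionality
    0 by convention, and angle 0 with the ``degenerate`` flag set.
    """
    if len(track.entries) < 2:
        raise ValueError("metrics need a track with at least 2 entries")
    if wound_direction not in (+1, -1):
        raise ValueError("wound_direction must be +1 or -1")
    s = meta.pixel_size
    centers = track.centers()
    steps = np.diff(centers, axis=0)
    accumulated = s * float(np.linalg.norm(steps, axis=1).sum())
    net = centers[-1] - centers[0]
    euclidean = s * float(np.linalg.norm(net))
    elapsed_h = (len(track.entries) - 1) * meta.frame_interval / 60.0
    velocity = accumulated / elapsed_h
    directionality = euclidean / accumulated if accumulated > 0 else 0.0
    y_fmi = s * wound_direction * float(net[1]) / accumulated if accumulated > 0 else 0.0
    dx, dyw = float(net[0]), wound_direction * float(net[1])
    degenerate = euclidean == 0.0
    angle = 0.0 if degenerate else math.degrees(math.atan2(dyw, dx)) % 360.0
    return MigrationMetrics(
        euclidean_distance=euclidean,
        accumulated_distance=accumulated,
        velocity=velocity,
        directionality=directionality,
        y_fmi=y_fmi,
        end_point_angle=angle,
        degenerate=degenerate,
    )


def _u_statistic(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2)


@lru_cache(maxsize=8)
def _labeling_indices(n_total: int, n_x: int) -> np.ndarray:
    """All C(n_total, n_x) index sets assigning pooled observations to the
    first sample; cached because repeated tests reuse the same sizes."""
    return np.array(list(combinations(range(n_total), n_x)))


def mww_test(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "normal", "auto"] = "auto",
) -> tuple[float, float]:
    """Two-sample Wilcoxon-Mann-Whitney test; returns ``(U, two-sided p)``.

    ``exact`` enumerates the full permutation distribution of U (all
    ``C(n+m, n)`` group labelings; feasible for n+m <= 20, ties handled by
    midranks). ``normal`` uses the tie-corrected normal approximation with
    continuity correction. ``auto`` picks exact when n+m <= 20. The two-sided
    p-value is the permutation probability of a U at least as far from its
    null mean ``nm/2`` as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    if mode == "auto":
        mode = "exact" if n + m <= 20 else "normal"
    if mode == "normal":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.statistic), min(1.0, float(res.pvalue))
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n], n)
    center = n * m / 2.0
    idx = _labeling_indices(n + m, n)
    u_perm = ranks[idx].sum(axis=1) - n * (n + 1) / 2
    d_obs = abs(u_obs - center)
    p = float(np.mean(np.abs(u_perm - center) >= d_obs - 1e-9))
    return u_obs, p


def compare_groups(
    metrics_by_condition: Mapping[str, Sequence[MigrationMetrics]],
    alpha: float = 0.05,
    mode: Literal["exact", "normal", "auto"] = "auto",
    bonferroni: bool = False,
) -> list[GroupComparison]:
    """Pairwise condition comparisons for every metric.

    Emits one :class:`GroupComparison` per condition pair and metric (all six
    metrics). Raw pairwise p-values by default; set ``bonferroni`` to adjust
    for the number of emitted comparisons. Conditions with fewer than 2
    tracks are skipped with a warning.
    """
    usable = {}
    for name, ms in metrics_by_condition.items():
        if len(ms) < 2:
            warnings.warn(f"condition {name!r} has fewer than 2 tracks; skipped", stacklevel=2)
        else:
            usable[name] = ms
    if len(usable) < 2:
        raise ValueError("need at least 2 conditions with at least 2 tracks each")
    pairs = list(combinations(sorted(usable), 2))
    n_tests = len(pairs) * len(METRIC_NAMES)
    out = []
    for a, b in pairs:
        for metric in METRIC_NAMES:
            xs = [m.value(metric) for m in usable[a]]
            ys = [m.value(metric) for m in usable[b]]
            u, p = mww_test(xs, ys, mode=mode)
            if bonferroni:
                p = min(1.0, p * n_tests)
            out.append(GroupComparison(metric, a, b, u, p, p < alpha))
    return out
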