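"""Leading-edge identification and leading-edge track selection.

The wound in a scratch assay is a horizontal band empty of cells between two
confluent monolayers. Its two boundaries are found from the vertical
cell-density profile of a frame: detection centers are histogrammed into
horizontal row bins, smoothed, and the wound band is the contiguous run of
low-density bins around the global density minimum. Cells whose tracks start
within a margin of either boundary (on the monolayer side) are the
leading-edge cells whose trajectories the migration metrics summarise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import Detection, SequenceMeta
from .tracking import Track

__all__ = [
    "DensityProfile",
    "LeadingEdges",
    "EligibleTrack",
    "WoundClosedError",
    "row_density_profile",
    "identify_leading_edges",
    "select_leading_edge_tracks",
    "sample_tracks",
]


class WoundClosedError(Exception):
    """Raised when no low-density band exists: the wound has closed (or the
    frame is fully confluent). A signal, not a failure."""


@dataclass
class DensityProfile:
    """Vertical cell-density profile of one frame."""

    bin_height: float
    counts: np.ndarray  # raw detection-center counts, top to bottom
    smoothed: np.ndarray  # centered moving average with edge truncation

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class LeadingEdges:
    """The two horizontal wound-boundary rows of a frame: ``y_top`` is the
    lower boundary of the upper monolayer, ``y_bottom`` the upper boundary of
    the lower monolayer."""

    y_top: float
    y_bottom: float

    def __post_init__(self) -> None:
        if not (0 < self.y_top < self.y_bottom):
            raise ValueError(f"edges must satisfy 0 < y_top < y_bottom, got {self}")


@dataclass(frozen=True)
class EligibleTrack:
    """A leading-edge track with its wound direction: +1 means the wound lies
    toward +y (upper-monolayer cell), -1 toward -y (lower-monolayer cell)."""

    track: Track
    wound_direction: int  # +1 or -1


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; windows truncate at the array edges (each
    position averages only the bins that exist)."""
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return sums / norm


def row_density_profile(
    detections: Sequence[Detection],
    meta: SequenceMeta,
    bin_height: float = 10.0,
    smooth_window: int = 5,
) -> DensityProfile:
    """Histogram of detection-box centers into horizontal row bins.

    All detections must belong to one frame. Each box center contributes one
    count to its bin; the smoothed profile is a centered moving average with
    edge truncation.
    """
    if bin_height <= 0:
        raise ValueError("bin_height must be positive")
    frames = {d.frame for d in detections}
    if len(frames) > 1:
        raise ValueError(f"detections span multiple frames: {sorted(frames)}")
    n_bins = int(np.ceil(meta.height / bin_height))
    counts = np.zeros(n_bins)
    for d in detections:
        b = int(d.box.center[1] / bin_height)
        counts[min(b, n_bins - 1)] += 1
    return DensityProfile(bin_height, counts, _moving_average(counts, smooth_window))


def identify_leading_edges(profile: DensityProfile, alpha: float = 0.25) -> LeadingEdges:
    """Locate the wound band in a density profile.

    The plateau density is the median of the smoothed counts over bins above
    the profile's midrange; the wound band is the maximal contiguous run of
    bins with smoothed count below ``alpha * plateau`` that contains the
    global minimum. Each band boundary is then refined outward over raw
    sub-threshold bins, so the reported edge row sits at the bin boundary
    adjacent to the outermost cell-bearing bin rather than half a smoothing
    window inside the wound. Raises :class:`WoundClosedError` when no bin
    falls below the threshold.
    """
    s = np.asarray(profile.smoothed, dtype=float)
    if s.size < 3:
        raise ValueError("profile too short to contain a wound band")
    midrange = 0.5 * (s.min() + s.max())
    above = s > midrange
    if not above.any():
        raise WoundClosedError("no high-density plateau found")
    plateau = float(np.median(s[above]))
    threshold = alpha * plateau
    below = s < threshold
    if not below.any():
        raise WoundClosedError("no bin below the wound-density threshold; wound closed")
    # contiguous sub-threshold runs; the wound band is the one containing the
    # global minimum (with tied minima, e.g. several all-zero runs when the
    # image margins hold no cells, the longest / deepest run wins)
    runs: list[tuple[int, int]] = []
    k = 0
    while k < s.size:
        if below[k]:
            lo = k
            while k + 1 < s.size and below[k + 1]:
                k += 1
            runs.append((lo, k))
        k += 1
    smin = s.min()
    candidates = [r for r in runs if s[r[0] : r[1] + 1].min() <= smin + 1e-12]
    lo, hi = max(candidates, key=lambda r: (r[1] - r[0], -float(s[r[0] : r[1] + 1].mean())))
    raw = np.asarray(profile.counts, dtype=float)
    while lo > 0 and raw[lo - 1] < threshold:
        lo -= 1
    while hi < s.size - 1 and raw[hi + 1] < threshold:
        hi += 1
    y_top = lo * profile.bin_height
    y_bottom = (hi + 1) * profile.bin_height
    if y_top <= 0 or y_bottom >= profile.n_bins * profile.bin_height:
        raise WoundClosedError("wound band touches the image border; no two-sided wound")
    return LeadingEdges(y_top=y_top, y_bottom=y_bottom)


def select_leading_edge_tracks(
    tracks: Sequence[Track], edges: LeadingEdges, margin: float = 50.0
) -> list[EligibleTrack]:
    """Select tracks starting at the wound's leading edges.

    A track is eligible if its frame-1 box center lies within ``margin`` px of
    either edge on the monolayer side: in ``[y_top - margin, y_top]`` (wound
    direction +y) or ``[y_bottom, y_bottom + margin]`` (wound direction -y).
    Tracks starting inside the wound band or deeper in the monolayer are not
    leading-edge cells.
    """
    out = []
    for t in tracks:
        y = t.entries[0].box.center[1]
        if edges.y_top - margin <= y <= edges.y_top:
            out.append(EligibleTrack(t, +1))
        elif edges.y_bottom <= y <= edges.y_bottom + margin:
            out.append(EligibleTrack(t, -1))
    return out


def sample_tracks(
    eligible: Sequence[EligibleTrack], n: int = 20, seed: int = 0
) -> list[EligibleTrack]:
    """Uniform random sample of ``min(n, len(eligible))`` tracks without
    replacement, deterministic under ``seed``. Warns on a shortfall."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(eligible) < n:
        warnings.warn(
            f"only {len(eligible)} eligible leading-edge tracks available "
            f"(requested {n}); returning all of them",
            stacklevel=2,
        )
        return list(eligible)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]
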