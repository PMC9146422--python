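import numpy as np
import pytest

from scratchtrack.geometry import SequenceMeta
from scratchtrack.simulate import SimConfig, corrupt_detections, simulate_positions


@pytest.fixture(scope="session")
def unambiguous_movie():
    """A 22-frame movie whose inter-cell spacing (40 px) exceeds twice the
    largest per-frame displacement, so every association is unambiguous and a
    correct tracker must recover every ground-truth track exactly."""
    cfg = SimConfig(
        width=600,
        height=460,
        n_frames=22,
        wound_rows=(160.0, 300.0),
        spacing=40.0,
        grid_jitter_sd=2.0,
        step_mean=3.0,
        step_sd=0.8,
        lateral_sd=0.5,
        interior_jitter_sd=0.5,
        edge_depth=45.0,
        seed=5,
    )
    gt = simulate_positions(cfg)
    assert len(gt.tracks) >= 100
    return gt


@pytest.fixture(scope="session")
def clean_detections(unambiguous_movie):
    return corrupt_detections(unambiguous_movie, p_miss=0.0, fp_per_frame=0, jitter_sd=0.0)


@pytest.fixture()
def meta_1um():
    """Convenience metadata with 1 um/px so pixel and micron values agree."""
    return SequenceMeta(width=500, height=500, n_frames=22, frame_interval=30.0, pixel_size=1.0)


def make_track(centers, start_frame=1, side=10.0, track_id=1, interpolated=None):
    """Build a Track from a list of (x, y) centers on consecutive frames."""
    from scratchtrack.geometry import BoundingBox
    from scratchtrack.tracking import Track, TrackEntry

    interpolated = interpolated or [False] * len(centers)
    entries = [
        TrackEntry(start_frame + k, BoundingBox.from_center(x, y, side, side), interp)
        for k, ((x, y), interp) in enumerate(zip(centers, interpolated))
    ]
    return Track(track_id, entries)


@pytest.fixture()
def track_factory():
    return make_track
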