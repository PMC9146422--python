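import numpy as np
import pytest

from scratchtrack.geometry import SequenceMeta
from scratchtrack.metrics import (
    METRIC_NAMES,
    MigrationMetrics,
    compare_groups,
    compute_metrics,
    mww_test,
)


class TestComputeMetrics:
    def test_single_step_track_at_assay_pixel_size(self, track_factory):
        meta = SequenceMeta(100, 100, 2, frame_interval=30.0, pixel_size=1.33)
        m = compute_metrics(track_factory([(20.5, 20.5), (23.5, 24.5)]), meta, +1)
        assert m.euclidean_distance == pytest.approx(6.65)
        assert m.accumulated_distance == pytest.approx(6.65)
        assert m.directionality == pytest.approx(1.0)
        assert m.velocity == pytest.approx(13.3)

    def test_three_four_five_construction(self, track_factory, meta_1um):
        m = compute_metrics(track_factory([(20.5, 20.5), (23.5, 24.5), (20.5, 28.5)]), meta_1um, +1)
        assert m.accumulated_distance == pytest.approx(10.0)
        assert m.euclidean_distance == pytest.approx(8.0)
        assert m.directionality == pytest.approx(0.8)
        assert m.y_fmi == pytest.approx(0.8)

    def test_stationary_track_is_degenerate(self, track_factory, meta_1um):
        m = compute_metrics(track_factory([(10, 10), (10, 10), (10, 10)]), meta_1um, +1)
        assert m.euclidean_distance == 0 and m.accumulated_distance == 0
        assert m.directionality == 0 and m.end_point_angle == 0
        assert m.degenerate

    def test_wound_ward_motion_maps_to_90_degrees(self, track_factory, meta_1um):
        down = track_factory([(50, 50), (50, 60)])
        up = track_factory([(50, 60), (50, 50)])
        assert compute_metrics(down, meta_1um, +1).end_point_angle == pytest.approx(90.0)
        assert compute_metrics(up, meta_1um, -1).end_point_angle == pytest.approx(90.0)
        assert compute_metrics(down, meta_1um, +1).y_fmi > 0
        assert compute_metrics(up, meta_1um, -1).y_fmi > 0

    def test_accumulated_bounds_euclidean_on_random_walks(self, track_factory, meta_1um):
        rng = np.random.default_rng(0)
        for _ in range(200):
            steps = rng.normal(0, 5, size=(rng.integers(2, 30), 2))
            centers = 300 + np.cumsum(steps, axis=0)
            m = compute_metrics(track_factory([tuple(c) for c in centers]), meta_1um, +1)
            assert m.accumulated_distance >= m.euclidean_distance - 1e-9
            assert abs(m.y_fmi) <= m.directionality + 1e-9

    def test_translation_invariance_and_rotation_equivariance(self, track_factory, meta_1um):
        rng = np.random.default_rng(1)
        centers = 200 + np.cumsum(rng.normal(0, 4, size=(10, 2)), axis=0)
        m0 = compute_metrics(track_factory([tuple(c) for c in centers]), meta_1um, +1)
        shifted = centers + np.array([55.0, -17.0])
        m1 = compute_metrics(track_factory([tuple(c) for c in shifted]), meta_1um, +1)
        for name in ("euclidean_distance", "accumulated_distance", "velocity", "directionality", "y_fmi", "end_point_angle"):
            assert getattr(m0, name) == pytest.approx(getattr(m1, name))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = 300 + (centers - 300) @ rot.T
        m2 = compute_metrics(track_factory([tuple(c) for c in rotated]), meta_1um, +1)
        for name in ("euclidean_distance", "accumulated_distance", "velocity", "directionality"):
            assert getattr(m0, name) == pytest.approx(getattr(m2, name))

    def test_too_short_track_rejected(self, track_factory, meta_1um):
        with pytest.raises(ValueError):
            compute_metrics(track_factory([(1, 1)]), meta_1um, +1)


class TestMwwTest:
    def test_fully_separated_samples_exact_p(self):
        u, p = mww_test([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = mww_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0], mode="exact")
        assert p == pytest.approx(1.0)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            x, y = rng.normal(size=8), rng.normal(size=8)
            _, pe = mww_test(x, y, mode="exact")
            _, pn = mww_test(x, y, mode="normal")
            assert abs(pe - pn) < 0.02

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(42)
        n_rep = 2000
        rejections = sum(
            mww_test(rng.normal(size=8), rng.normal(size=8), mode="exact")[1] < 0.05
            for _ in range(n_rep)
        )
        assert abs(rejections / n_rep - 0.05) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mww_test([], [1.0])


def _metrics(vals):
    return [
        MigrationMetrics(v, v + 1, v, 0.5, 0.3, 90.0) for v in vals
    ]


class TestCompareGroups:
    def test_identical_groups_never_significant(self):
        groups = {"a": _metrics([1, 2, 3, 4]), "b": _metrics([1, 2, 3, 4])}
        out = compare_groups(groups)
        assert len(out) == 6
        assert not any(c.significant for c in out)

    def test_three_conditions_give_18_comparisons(self):
        rng = np.random.default_rng(0)
        groups = {k: _metrics(rng.normal(size=5)) for k in ("a", "b", "c")}
        assert len(compare_groups(groups)) == 18

    def test_small_condition_skipped_with_warning(self):
        groups = {"a": _metrics([1, 2, 3]), "b": _metrics([4, 5, 6]), "tiny": _metrics([1])}
        with pytest.warns(UserWarning, match="tiny"):
            out = compare_groups(groups)
        assert {(c.group_a, c.group_b) for c in out} == {("a", "b")}

    def test_separated_groups_detected(self):
        groups = {"lo": _metrics([1, 2, 3, 4, 5]), "hi": _metrics([10, 11, 12, 13, 14])}
        out = compare_groups(groups)
        eu = [c for c in out if c.metric == "euclidean_distance"][0]
        assert eu.significant and eu.p_value < 0.05
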