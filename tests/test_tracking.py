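from itertools import permutations

import numpy as np
import pytest

from scratchtrack.geometry import BoundingBox, Detection
from scratchtrack.simulate import corrupt_detections
from scratchtrack.tracking import (
    AffinityConfig,
    Track,
    TrackEntry,
    appearance_features,
    associate_tracklets,
    cleave_tracklets,
    combined_affinity,
    filter_complete_tracks,
    group_by_frame,
    link_frames,
    motion_features,
    solve_assignment,
    track_detections,
)


def brute_force_min_cost(cost):
    """Exhaustive minimum over all one-to-one matchings of a rectangular
    cost matrix (rows <= cols)."""
    n, m = cost.shape
    assert n <= m
    best = np.inf
    for perm in permutations(range(m), n):
        best = min(best, sum(cost[i, j] for i, j in enumerate(perm)))
    return best


class TestAppearanceFeatures:
    def test_identical_patches_score_one(self):
        rng = np.random.default_rng(0)
        p = rng.random((12, 12))
        assert appearance_features(p, p) == pytest.approx((1.0, 1.0))

    def test_photometric_inversion_kills_ncc(self):
        rng = np.random.default_rng(1)
        p = rng.random((16, 16))
        ncc, _ = appearance_features(p, 1.0 - p)
        assert ncc == pytest.approx(0.0, abs=1e-9)

    def test_equal_constant_patches_fall_back_to_one(self):
        p = np.full((8, 8), 0.4)
        assert appearance_features(p, p.copy()) == pytest.approx((1.0, 1.0))

    def test_different_sizes_are_resampled(self):
        rng = np.random.default_rng(2)
        p = rng.random((20, 20))
        scores = appearance_features(p, p[::2, ::2])
        assert all(0 <= s <= 1 for s in scores)


class TestMotionFeatures:
    def make_tail(self, centers):
        entries = [
            TrackEntry(k + 1, BoundingBox.from_center(x, y, 10, 10))
            for k, (x, y) in enumerate(centers)
        ]
        return Track(1, entries)

    def test_stationary_redetection(self):
        tail = self.make_tail([(50, 50)])
        cand = Detection(2, BoundingBox.from_center(50, 50, 10, 10))
        f1, f2, f3, f4 = motion_features(tail, cand, gate_px=25)
        assert (f1, f2, f3) == (1.0, 1.0, 1.0)
        assert f4 == 0.5  # no history: neutral direction score

    def test_displacement_at_gate_scores_zero(self):
        tail = self.make_tail([(50, 50)])
        cand = Detection(2, BoundingBox.from_center(75, 50, 10, 10))
        f1, *_ = motion_features(tail, cand, gate_px=25)
        assert f1 == pytest.approx(0.0)

    def test_straight_mover_has_perfect_direction_score(self):
        tail = self.make_tail([(10, 50), (20, 50)])
        cand = Detection(3, BoundingBox.from_center(30, 50, 10, 10))
        *_, f4 = motion_features(tail, cand, gate_px=25)
        assert f4 == pytest.approx(1.0)

    def test_non_causal_candidate_rejected(self):
        tail = self.make_tail([(10, 50), (20, 50)])
        with pytest.raises(ValueError):
            motion_features(tail, Detection(2, BoundingBox.from_center(0, 0, 10, 10)), 25)


class TestCombinedAffinity:
    cfg = AffinityConfig(w_app=(1 / 6, 1 / 6), w_mot=(1 / 6, 1 / 6, 1 / 6, 1 / 6))

    @pytest.mark.parametrize(
        "app, mot, expected",
        [((1, 1), (1, 1, 1, 1), 1.0), ((0, 0), (0, 0, 0, 0), 0.0), ((1, 1), (1, 1, 0, 0), 2 / 3)],
    )
    def test_weighted_sum(self, app, mot, expected):
        assert combined_affinity(app, mot, self.cfg) == pytest.approx(expected)

    def test_monotone_in_every_score(self):
        rng = np.random.default_rng(3)
        base = rng.random(6)
        v0 = combined_affinity(base[:2], base[2:], AffinityConfig())
        for k in range(6):
            bumped = base.copy()
            bumped[k] = min(1.0, bumped[k] + 0.2)
            assert combined_affinity(bumped[:2], bumped[2:], AffinityConfig()) >= v0 - 1e-12

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            AffinityConfig(w_app=(0.5, 0.5), w_mot=(0.5, 0.0, 0.0, 0.0))


class TestSolveAssignment:
    def test_two_by_two(self):
        matches, ur, uc = solve_assignment(np.array([[1.0, 2.0], [2.0, 1.0]]), gate_cost=10)
        assert matches == [(0, 0), (1, 1)] and not ur and not uc

    def test_matches_exhaustive_minimum_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = rng.integers(1, 7)
            m = rng.integers(n, 7)
            cost = rng.random((n, m)) * 10
            matches, _, _ = solve_assignment(cost, gate_cost=np.inf)
            total = sum(cost[r, c] for r, c in matches)
            assert total == pytest.approx(brute_force_min_cost(cost))

    def test_gating_severs_expensive_pairs(self):
        matches, ur, uc = solve_assignment(np.array([[5.0]]), gate_cost=1.0)
        assert matches == [] and ur == [0] and uc == [0]

    def test_empty_matrix(self):
        matches, ur, uc = solve_assignment(np.empty((0, 0)), gate_cost=1.0)
        assert matches == [] and ur == [] and uc == []


def _line_detections(start, step, n_frames, frame0=1, side=10.0):
    x, y = start
    return [
        Detection(frame0 + t, BoundingBox.from_center(x + step[0] * t, y + step[1] * t, side, side))
        for t in range(n_frames)
    ]


class TestLinkFrames:
    def test_two_separated_movers_yield_two_tracklets(self):
        dets = _line_detections((50, 50), (5, 0), 5) + _line_detections((50, 250), (5, 0), 5)
        tracklets = link_frames(group_by_frame(dets))
        assert len(tracklets) == 2
        assert sorted(len(t.entries) for t in tracklets) == [5, 5]

    def test_lone_detection_becomes_singleton(self):
        dets = {1: [Detection(1, BoundingBox.from_center(50, 50, 10, 10))]}
        tracklets = link_frames(dets)
        assert len(tracklets) == 1 and len(tracklets[0].entries) == 1

    def test_pure_motion_linking_follows_a_line(self):
        cfg = AffinityConfig(w_app=(0.0, 0.0), w_mot=(0.45, 0.25, 0.15, 0.15))
        dets = _line_detections((10, 10), (8, 3), 6)
        tracklets = link_frames(group_by_frame(dets), cfg)
        assert len(tracklets) == 1 and len(tracklets[0].entries) == 6

    def test_every_detection_lands_in_exactly_one_tracklet(self, clean_detections):
        tracklets = link_frames(clean_detections)
        n_in = sum(len(v) for v in clean_detections.values())
        n_out = sum(len(t.entries) for t in tracklets)
        assert n_in == n_out
        seen = set()
        for t in tracklets:
            for e in t.entries:
                key = (e.frame, e.box.x_min, e.box.y_min)
                assert key not in seen
                seen.add(key)

    def test_lower_affinity_floor_never_loses_links(self, clean_detections):
        def n_links(floor):
            cfg = AffinityConfig(affinity_floor=floor)
            tracklets = link_frames(clean_detections, cfg)
            return sum(len(t.entries) - 1 for t in tracklets)

        counts = [n_links(f) for f in (0.6, 0.4, 0.2, 0.0)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestAssociateTracklets:
    def test_gap_closed_with_interpolated_entry(self, track_factory):
        left = track_factory([(100, 90), (100, 95), (100, 100)], start_frame=3, track_id=1)
        right = track_factory([(100, 110), (100, 115)], start_frame=7, track_id=2)
        cfg = AffinityConfig(gate_px=10, max_gap_frames=3)
        merged = associate_tracklets([left, right], cfg)
        assert len(merged) == 1
        track = merged[0]
        assert [e.frame for e in track.entries] == [3, 4, 5, 6, 7, 8]
        interp = [e for e in track.entries if e.interpolated]
        assert len(interp) == 1 and interp[0].frame == 6
        cx, cy = interp[0].box.center
        assert (cx, cy) == pytest.approx((100, 105), abs=1.0)
        assert interp[0].confidence == 0.0

    def test_gap_beyond_limit_not_merged(self, track_factory):
        left = track_factory([(100, 90), (100, 95), (100, 100)], start_frame=1, track_id=1)
        right = track_factory([(100, 120), (100, 125)], start_frame=8, track_id=2)  # gap 4
        cfg = AffinityConfig(gate_px=10, max_gap_frames=2)
        assert len(associate_tracklets([left, right], cfg)) == 2

    def test_globally_cheaper_pairing_wins(self, track_factory):
        # one ended tracklet, two possible continuations; then a second ended
        # tracklet for which only the worse continuation remains feasible
        a = track_factory([(100, 100), (105, 100)], start_frame=1, track_id=1)
        b = track_factory([(100, 140), (105, 140)], start_frame=1, track_id=2)
        cont_a = track_factory([(115, 101), (120, 101)], start_frame=4, track_id=3)
        cont_b = track_factory([(115, 139), (120, 139)], start_frame=4, track_id=4)
        cfg = AffinityConfig(gate_px=25, max_gap_frames=2)
        merged = associate_tracklets([a, b, cont_a, cont_b], cfg)
        assert len(merged) == 2
        for t in merged:
            ys = {round(e.box.center[1] / 20) for e in t.entries}
            assert len(ys) == 1  # each chain stays on its own row


class TestCleave:
    def test_jump_is_cut(self, track_factory):
        centers = [(10 + 5 * k, 50) for k in range(5)] + [(10 + 20 + 60 + 5 * k, 50) for k in range(4)]
        track = track_factory(centers)
        frags = cleave_tracklets([track], AffinityConfig(cleave_factor=4.0))
        assert len(frags) == 2
        assert [len(f.entries) for f in frags] == [5, 4]

    def test_uniform_track_unchanged(self, track_factory):
        track = track_factory([(10 + 5 * k, 50) for k in range(8)])
        frags = cleave_tracklets([track], AffinityConfig())
        assert len(frags) == 1 and len(frags[0].entries) == 8

    def test_short_tracks_never_cleaved(self, track_factory):
        track = track_factory([(10, 50), (200, 50)])
        assert len(cleave_tracklets([track], AffinityConfig())) == 1

    def test_identity_switch_fixed_by_cleave_and_reassociation(self, track_factory):
        # two parallel movers whose identities were swapped mid-sequence:
        # each mislinked track contains a 60 px vertical jump at the splice
        a_pts = [(10 + 5 * k, 100) for k in range(10)]
        b_pts = [(10 + 5 * k, 160) for k in range(10)]
        bad1 = track_factory(a_pts[:5] + b_pts[5:], track_id=1)
        bad2 = track_factory(b_pts[:5] + a_pts[5:], track_id=2)
        cfg = AffinityConfig(gate_px=15, max_gap_frames=2, cleave_factor=4.0)
        fixed = associate_tracklets([bad1, bad2], cfg)
        assert len(fixed) == 2
        for t in fixed:
            ys = {e.box.center[1] for e in t.entries}
            assert ys in ({100.0}, {160.0})  # identities untangled


class TestFilterCompleteTracks:
    def test_interpolated_entries_count_as_present(self, track_factory):
        interp = [False] * 22
        interp[5] = interp[11] = True
        track = track_factory([(10 + k, 50) for k in range(22)], interpolated=interp)
        assert filter_complete_tracks([track], 22) == [track]

    def test_late_start_excluded(self, track_factory):
        track = track_factory([(10 + k, 50) for k in range(21)], start_frame=2)
        assert filter_complete_tracks([track], 22) == []

    def test_empty_input(self):
        assert filter_complete_tracks([], 22) == []

    def test_invalid_n_frames(self):
        with pytest.raises(ValueError):
            filter_complete_tracks([], 1)


class TestEndToEndRecovery:
    def test_gap_robustness_with_missed_detections(self, unambiguous_movie):
        from scratchtrack.evaluate import detection_complete_recovery

        dets = corrupt_detections(unambiguous_movie, p_miss=0.1, fp_per_frame=0, jitter_sd=0.0, seed=7)
        tracks = track_detections(dets, AffinityConfig())
        assert detection_complete_recovery(unambiguous_movie.tracks, tracks) >= 0.9
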