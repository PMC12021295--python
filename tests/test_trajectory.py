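"""Trajectory measures, motion segmentation and directional statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spotlink.config import TrajectoryParams
from spotlink.core import Detection, ImageSequence, MissingMetadataError, Track
from spotlink.trajectory import (
    AxisFrame,
    axis_displacement,
    classify_direction,
    framewise_pearson,
    max_segment_speed,
    measures,
    polar_histogram,
    segment_motion,
)


def _track(pts, frames=None, tid=0, roi_mean=10.0):
    frames = frames if frames is not None else range(len(pts))
    return Track(id=tid, detections=[
        Detection(frame=f, x=float(x), y=float(y), roi_mean=roi_mean)
        for f, (x, y) in zip(frames, pts)
    ])


class TestMeasures:
    def test_three_four_five_track(self):
        """3-4-5 steps at 100 nm/px, 0.5 s/frame: 1 µm in 1 s."""
        t = _track([(0, 0), (3, 4), (6, 8)])
        m = measures(t, frame_interval_s=0.5, pixel_size_nm=100.0)
        assert m.d_total_um == pytest.approx(1.0)
        assert m.d_net_um == pytest.approx(1.0)
        assert m.t_traj_s == pytest.approx(1.0)
        assert m.v_curvilinear_um_s == pytest.approx(1.0)
        assert m.v_line_um_s == pytest.approx(1.0)

    def test_out_and_back(self):
        t = _track([(0, 0), (3, 4), (0, 0)])
        m = measures(t, frame_interval_s=0.5, pixel_size_nm=100.0)
        assert m.d_net_um == 0.0
        assert m.v_line_um_s == 0.0
        assert m.d_total_um == pytest.approx(1.0)
        assert m.d_max_um == pytest.approx(0.5)

    def test_theta_matches_step_heading(self):
        # step along +x: theta 0; step "up" (decreasing row): theta 90
        m = measures(_track([(0, 0), (5, 0)]), 0.5, 100.0)
        assert m.theta_net_deg == pytest.approx(0.0)
        m = measures(_track([(0, 5), (0, 0)]), 0.5, 100.0)
        assert m.theta_net_deg == pytest.approx(90.0)

    def test_gap_frames_count_toward_time(self):
        t = _track([(0, 0), (10, 0)], frames=[0, 4])
        m = measures(t, frame_interval_s=0.5, pixel_size_nm=1000.0)
        assert m.t_traj_s == pytest.approx(2.0)
        assert m.v_line_um_s == pytest.approx(5.0)

    def test_brightness_normalized_by_sequence_max(self):
        t = _track([(0, 0), (1, 0)], roi_mean=50.0)
        m = measures(t, 0.5, 100.0, b_max=200.0)
        assert m.b_mean == pytest.approx(0.25)

    def test_metadata_required(self):
        with pytest.raises(MissingMetadataError):
            measures(_track([(0, 0), (1, 1)]), None, None)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(
        st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
        min_size=2, max_size=12,
    ))
    def test_distance_and_speed_orderings(self, pts):
        m = measures(_track(pts), 0.5, 100.0)
        assert m.d_net_um <= m.d_max_um + 1e-9
        assert m.d_max_um <= m.d_total_um + 1e-9
        assert m.v_line_um_s <= m.v_curvilinear_um_s + 1e-9


class TestSegmentMotion:
    def test_ballistic_track_is_one_segment(self):
        t = _track([(i * 2.0, 0) for i in range(20)])
        labels, segments = segment_motion(t)
        assert labels.all()
        assert len(segments) == 1
        assert segments[0] == (0, 19)

    def test_stationary_jitter_no_segments(self, rng):
        pts = rng.normal(0, 0.1, (30, 2))
        labels, segments = segment_motion(_track(pts))
        assert len(segments) == 0

    def test_move_pause_move_two_segments(self, rng):
        run1 = [(i * 2.0, 0.0) for i in range(12)]
        pause = [(22.0 + rng.normal(0, 0.05), rng.normal(0, 0.05))
                 for _ in range(12)]
        run2 = [(24.0 + i * 2.0, 0.0) for i in range(12)]
        t = _track(run1 + pause + run2)
        labels, segments = segment_motion(t)
        assert len(segments) == 2
        # average moving time = mean of the two segment durations
        params = TrajectoryParams()
        m = measures(t, 0.5, 100.0, segment_params=params)
        d1 = (segments[0][1] - segments[0][0]) * 0.5
        d2 = (segments[1][1] - segments[1][0]) * 0.5
        assert m.t_avg_moving_s == pytest.approx((d1 + d2) / 2)

    def test_short_track_unsegmentable(self):
        labels, segments = segment_motion(_track([(0, 0), (1, 0), (2, 0)]))
        assert labels is None and segments == []


class TestMaxSegmentSpeed:
    def test_constant_speed_track(self):
        # 2 px/frame at 100 nm/px, 4 fps → 0.8 µm/s
        t = _track([(i * 2.0, 0) for i in range(20)])
        _, segments = segment_motion(t)
        v = max_segment_speed(t, segments, window_s=1.0,
                              frame_interval_s=0.25, pixel_size_nm=100.0)
        assert v == pytest.approx(0.8, rel=1e-6)

    def test_fast_stretch_dominates(self):
        slow = [(i * 0.25, 0.0) for i in range(10)]       # 1 µm/s at 4 fps
        fast = [(2.25 + i * 0.5, 0.0) for i in range(10)]  # 2 µm/s
        t = _track(slow + fast)
        _, segments = segment_motion(t)
        v = max_segment_speed(t, segments, 1.0, 0.25, 1000.0)
        assert v == pytest.approx(2.0, rel=0.01)

    def test_window_longer_than_segments_flagged(self):
        t = _track([(i * 2.0, 0) for i in range(6)])
        v = max_segment_speed(t, [(0, 2)], window_s=10.0,
                              frame_interval_s=0.25, pixel_size_nm=100.0)
        assert v is None


class TestClassifyDirection:
    axis = AxisFrame(apical_angle_deg=90.0)

    @pytest.mark.parametrize("theta,expected", [
        (100.0, "apical"),   # |100-90| = 10 ≤ 45
        (140.0, "lateral"),
        (270.0, "basal"),
        (45.0, "apical"),    # tie goes to axial class
        (315.0, "basal"),
    ])
    def test_quadrants(self, theta, expected):
        assert classify_direction(theta, self.axis) == expected

    def test_planar_labels(self):
        axis = AxisFrame(leading_angle_deg=0.0)
        assert classify_direction(10.0, axis, planar=True) == "leading"
        assert classify_direction(180.0, axis, planar=True) == "trailing"
        assert classify_direction(90.0, axis, planar=True) == "perpendicular"

    def test_isotropic_fractions(self, rng):
        thetas = rng.uniform(0, 360, 10000)
        labels = [classify_direction(t, self.axis) for t in thetas]
        n = len(labels)
        frac_ap = labels.count("apical") / n
        frac_lat = labels.count("lateral") / n
        frac_ba = labels.count("basal") / n
        # binomial sd ≈ 0.43/100 ≈ 0.004; allow 4 sd
        assert frac_ap == pytest.approx(0.25, abs=0.02)
        assert frac_lat == pytest.approx(0.50, abs=0.02)
        assert frac_ba == pytest.approx(0.25, abs=0.02)


class TestPolarHistogram:
    def test_binning_and_normalization(self):
        h = polar_histogram(np.array([5.0, 12.0, 355.0]),
                            np.array([2.0, 2.0, 2.0]), duration_min=2.0)
        assert h.counts[0] == 1 and h.counts[1] == 1 and h.counts[35] == 1
        assert h.counts_per_min[0] == pytest.approx(0.5)
        assert h.counts.sum() == h.n_included == 3

    def test_short_track_excluded(self):
        h = polar_histogram(np.array([5.0]), np.array([0.8]), 1.0)
        assert h.counts.sum() == 0 and h.n_excluded == 1

    def test_360_wraps_to_first_bin(self):
        h = polar_histogram(np.array([360.0]), np.array([2.0]), 1.0)
        assert h.counts[0] == 1

    def test_counts_sum_to_included(self, rng):
        theta = rng.uniform(0, 360, 500)
        dnet = rng.uniform(0, 3, 500)
        h = polar_histogram(theta, dnet, 4.0)
        assert h.counts.sum() == h.n_included == (dnet >= 1.0).sum()


class TestAxisDisplacement:
    axis = AxisFrame(apical_angle_deg=90.0)

    def test_along_apical_positive(self):
        # apical = up = decreasing row
        t = _track([(0, 30), (0, 0)])
        assert axis_displacement(t, self.axis, 100.0) == pytest.approx(3.0)

    def test_basal_negative(self):
        t = _track([(0, 0), (0, 20)])
        assert axis_displacement(t, self.axis, 100.0) == pytest.approx(-2.0)

    def test_perpendicular_zero(self):
        t = _track([(0, 0), (20, 0)])
        assert axis_displacement(t, self.axis, 100.0) == pytest.approx(0.0)

    def test_linear_in_concatenation(self, rng):
        pts = rng.uniform(0, 50, (6, 2))
        whole = _track(pts)
        part1 = _track(pts[:3])
        part2 = _track(pts[2:], frames=range(2, 6))
        d_whole = axis_displacement(whole, self.axis, 100.0)
        d_parts = (axis_displacement(part1, self.axis, 100.0)
                   + axis_displacement(part2, self.axis, 100.0))
        assert d_whole == pytest.approx(d_parts)


class TestFramewisePearson:
    def _seq(self, arr):
        return ImageSequence(frames=np.asarray(arr, dtype=float))

    def test_identical_sequences_r1(self, rng):
        a = rng.uniform(0, 100, (5, 16, 16))
        r, _ = framewise_pearson(self._seq(a), self._seq(a))
        assert np.allclose(r, 1.0)

    def test_negated_sequences_r_minus1(self, rng):
        a = rng.uniform(0, 100, (3, 16, 16))
        b = a.mean(axis=(1, 2), keepdims=True) * 2 - a
        r, _ = framewise_pearson(self._seq(a), self._seq(b))
        assert np.allclose(r, -1.0)

    def test_independent_noise_near_zero(self, rng):
        a = rng.uniform(0, 100, (40, 64, 64))
        b = rng.uniform(0, 100, (40, 64, 64))
        r, _ = framewise_pearson(self._seq(a), self._seq(b))
        assert (np.abs(r) < 0.1).mean() >= 0.95

    def test_constant_frame_flagged_nan(self, rng):
        a = rng.uniform(0, 100, (2, 8, 8))
        b = a.copy()
        b[1] = 5.0
        r, _ = framewise_pearson(self._seq(a), self._seq(b))
        assert math.isnan(r[1]) and not math.isnan(r[0])

    def test_normalization_peak_is_one(self, rng):
        a = rng.uniform(0, 100, (6, 16, 16))
        b = a + rng.uniform(0, 50, (6, 16, 16))
        r, norm = framewise_pearson(self._seq(a), self._seq(b))
        assert norm[0] == pytest.approx(0.0)
        assert np.nanmax(np.abs(norm)) == pytest.approx(1.0)
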