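"""Assignment, tracklet formation, connectivity scoring and assembly."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from spotlink.bayesnet import DiscreteBayesNet
from spotlink.config import LinkParams, default_cpts
from spotlink.core import Detection, Track
from spotlink.link import (
    assign,
    build_connectivity_net,
    filter_tracks,
    form_tracklets,
    link_tracklets,
    multi_pass,
    pair_evidence,
    score_pair,
)


def brute_force_min_cost(costs: np.ndarray) -> float:
    """Independent oracle: enumerate all permutations."""
    n, m = costs.shape
    best = math.inf
    k = min(n, m)
    rows = range(n)
    for rsub in itertools.permutations(rows, k):
        total = sum(costs[r, c] for c, r in enumerate(rsub))
        best = min(best, total)
    return best


def _det(frame, x, y, roi_mean=10.0):
    return Detection(frame=frame, x=float(x), y=float(y), roi_mean=roi_mean)


def _tracklet(tid, pts, start=0, step=1, roi_mean=10.0):
    return Track(id=tid, detections=[
        _det(start + i * step, x, y, roi_mean) for i, (x, y) in enumerate(pts)
    ])


class TestAssign:
    def test_two_by_two_diagonal(self):
        pairs, ur, uc = assign(np.array([[1.0, 5.0], [5.0, 1.0]]))
        assert sorted(pairs) == [(0, 0), (1, 1)]
        assert not ur and not uc

    def test_gate_blocks_single_match(self):
        pairs, ur, uc = assign(np.array([[3.0]]), gate=2.0)
        assert pairs == [] and ur == [0] and uc == [0]

    def test_matches_brute_force_on_random_squares(self, rng):
        for _ in range(20):
            c = rng.uniform(0, 10, (5, 5))
            pairs, _, _ = assign(c)
            total = sum(c[r, col] for r, col in pairs)
            assert total == pytest.approx(brute_force_min_cost(c))

    def test_rectangular_leaves_extras_unmatched(self, rng):
        c = rng.uniform(0, 1, (2, 4))
        pairs, ur, uc = assign(c)
        assert len(pairs) == 2 and not ur and len(uc) == 2

    def test_infinite_cost_rejected(self):
        with pytest.raises(ValueError):
            assign(np.array([[np.inf]]))


class TestFormTracklets:
    params = LinkParams()

    def test_single_chain(self):
        dets = [[_det(0, 0, 0)], [_det(1, 1, 0)], [_det(2, 2, 0)]]
        tl = form_tracklets(dets, LinkParams(max_link_dist_px=2.0))
        assert len(tl) == 1 and len(tl[0]) == 3

    def test_parallel_particles_no_swap(self):
        dets = [
            [_det(f, f * 1.0, 0.0), _det(f, f * 1.0, 10.0)] for f in range(5)
        ]
        tl = form_tracklets(dets, LinkParams(max_link_dist_px=2.0))
        assert len(tl) == 2
        for t in tl:
            ys = {d.y for d in t}
            assert len(ys) == 1  # each tracklet stays in its own lane

    def test_gap_bridged_within_missed_frames(self):
        dets = [[_det(0, 0, 0)], [], [_det(2, 1, 0)]]
        tl = form_tracklets(dets, LinkParams(max_link_dist_px=2.0,
                                             max_missed_frames=1))
        assert len(tl) == 1
        assert list(tl[0].frames) == [0, 2]

    def test_large_step_opens_new_tracklet(self):
        dets = [[_det(0, 0, 0)], [_det(1, 5, 0)]]
        tl = form_tracklets(dets, LinkParams(max_link_dist_px=2.0))
        assert len(tl) == 2

    def test_length_cap_closes_tracklet(self):
        dets = [[_det(f, f * 0.5, 0)] for f in range(25)]
        tl = form_tracklets(dets, LinkParams(max_link_dist_px=2.0,
                                             max_tracklet_len=10))
        assert all(len(t) <= 10 for t in tl)
        assert sum(len(t) for t in tl) == 25


class TestBayesNet:
    def test_cpt_shape_validation(self):
        net = DiscreteBayesNet()
        net.add_node("a", 2, cpt=[0.5, 0.5])
        with pytest.raises(ValueError, match="shape"):
            net.add_node("b", 2, parents=["a"], cpt=[0.5, 0.5])
        with pytest.raises(ValueError, match="sum"):
            net.add_node("b", 2, parents=["a"], cpt=[[0.9, 0.3], [0.5, 0.5]])

    def test_posterior_matches_hand_enumeration(self):
        """Oracle: direct Bayes computation on a 3-node net."""
        net = DiscreteBayesNet()
        net.add_node("cause", 2, cpt=[0.3, 0.7])
        net.add_node("e1", 2, parents=["cause"], cpt=[[0.9, 0.1], [0.2, 0.8]])
        net.add_node("e2", 2, parents=["cause"], cpt=[[0.6, 0.4], [0.5, 0.5]])
        post = net.posterior("cause", {"e1": 0, "e2": 0})
        # hand enumeration: P(c=0)∝0.3·0.9·0.6, P(c=1)∝0.7·0.2·0.5
        p0 = 0.3 * 0.9 * 0.6
        p1 = 0.7 * 0.2 * 0.5
        assert post[0] == pytest.approx(p0 / (p0 + p1))

    def test_unobserved_leaf_is_marginalized(self):
        net = DiscreteBayesNet()
        net.add_node("cause", 2, cpt=[0.3, 0.7])
        net.add_node("e1", 2, parents=["cause"], cpt=[[0.9, 0.1], [0.2, 0.8]])
        net.add_node("e2", 2, parents=["cause"], cpt=[[0.6, 0.4], [0.5, 0.5]])
        post = net.posterior("cause", {"e1": 0})
        p0, p1 = 0.3 * 0.9, 0.7 * 0.2
        assert post[0] == pytest.approx(p0 / (p0 + p1))


class TestScorePair:
    params = LinkParams()

    def _aligned_pair(self, reversed_b=False, gap=1, dist_x=2.0,
                      overlap=False):
        a = _tracklet(0, [(0, 0), (1, 0), (2, 0), (3, 0)])
        bx = 3.0 + dist_x
        pts = [(bx + i, 0) for i in range(4)]
        if reversed_b:
            pts = [(bx + 3 - i, 0) for i in range(4)]
        start = a.end_frame + gap if not overlap else a.end_frame
        b = _tracklet(1, pts, start=start)
        return a, b

    def test_probability_axioms(self):
        a, b = self._aligned_pair()
        s = score_pair(a, b, self.params)
        assert s is not None and 0.0 <= s.p_c <= 1.0
        net = build_connectivity_net(self.params.cpts)
        ev = pair_evidence(a, b, self.params)
        post = net.posterior("CS", {"seq": ev.seq, "gap": ev.gap,
                                    "distance": ev.distance,
                                    "intensity": ev.intensity,
                                    "orientation": ev.orientation,
                                    "speed": ev.speed})
        assert post.sum() == pytest.approx(1.0)

    def test_aligned_outscores_reversed_heading(self):
        a, b = self._aligned_pair()
        a2, b2 = self._aligned_pair(reversed_b=True)
        s_aligned = score_pair(a, b, self.params)
        s_reversed = score_pair(a2, b2, self.params)
        assert s_aligned.p_c > s_reversed.p_c

    def test_score_matches_enumeration_oracle(self):
        """Independent oracle: naive odds product over the evidence tables."""
        a, b = self._aligned_pair()
        ev = pair_evidence(a, b, self.params)
        cpts = default_cpts()
        odds = cpts["prior_true"] / (1 - cpts["prior_true"])
        for node, state in [("intensity", ev.intensity),
                            ("orientation", ev.orientation),
                            ("speed", ev.speed), ("seq", ev.seq),
                            ("gap", ev.gap), ("distance", ev.distance)]:
            odds *= cpts[node]["true"][state] / cpts[node]["false"][state]
        expected = odds / (1 + odds)
        s = score_pair(a, b, self.params)
        assert s.p_c == pytest.approx(expected, rel=1e-9)

    def test_out_of_gate_not_comparable(self):
        a, b = self._aligned_pair(gap=self.params.pair_gate_frames + 3)
        assert score_pair(a, b, self.params) is None
        a, b = self._aligned_pair(dist_x=self.params.pair_gate_px + 5)
        assert score_pair(a, b, self.params) is None

    def test_overlap_scores_no_higher_than_no_overlap(self):
        a, b = self._aligned_pair()
        a2, b2 = self._aligned_pair(overlap=True)
        s_plain = score_pair(a, b, self.params)
        s_overlap = score_pair(a2, b2, self.params)
        assert s_overlap.p_c <= s_plain.p_c

    def test_single_point_tracklet_uses_uninformative_motion(self):
        a = _tracklet(0, [(0, 0)])
        b = _tracklet(1, [(2, 0), (3, 0)], start=1)
        ev = pair_evidence(a, b, LinkParams())
        assert ev.orientation is None and ev.speed is None
        s = score_pair(a, b, LinkParams())
        assert s is not None and 0 <= s.p_c <= 1


class TestLinkTracklets:
    def test_split_trajectory_rejoined(self):
        params = LinkParams()
        a = _tracklet(0, [(i, 0) for i in range(5)])
        b = _tracklet(1, [(7 + i, 0) for i in range(5)], start=7)  # 2-frame gap
        tracks = link_tracklets([a, b], params)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_distant_simultaneous_tracklets_stay_separate(self):
        params = LinkParams()
        a = _tracklet(0, [(i, 0) for i in range(5)])
        b = _tracklet(1, [(i, 200) for i in range(5)])
        tracks = link_tracklets([a, b], params)
        assert len(tracks) == 2

    def test_detection_conservation(self, rng):
        params = LinkParams()
        tracklets = []
        for k in range(6):
            x0, y0 = rng.uniform(0, 100, 2)
            tracklets.append(
                _tracklet(k, [(x0 + i, y0) for i in range(4)],
                          start=int(rng.integers(0, 10)))
            )
        tracks = link_tracklets(tracklets, params)
        def key(d):
            return (d.frame, round(d.x, 6), round(d.y, 6))
        before = sorted(key(d) for t in tracklets for d in t)
        after = sorted(key(d) for t in tracks for d in t)
        assert before == after

    def test_frames_strictly_increase_after_joins(self):
        params = LinkParams()
        a = _tracklet(0, [(i, 0) for i in range(5)])
        b = _tracklet(1, [(6 + i, 0) for i in range(5)], start=6)
        c = _tracklet(2, [(12 + i, 0) for i in range(5)], start=12)
        tracks = link_tracklets([a, b, c], params)
        for t in tracks:
            f = list(t.frames)
            assert f == sorted(f) and len(set(f)) == len(f)


class TestMultiPass:
    def test_single_default_pass_equals_link_tracklets(self):
        params = LinkParams(passes=[{}])
        a = _tracklet(0, [(i, 0) for i in range(5)])
        b = _tracklet(1, [(7 + i, 0) for i in range(5)], start=7)
        t1 = link_tracklets([a, b], params)
        t2 = multi_pass([a, b], params)
        assert len(t1) == len(t2) == 1

    def test_second_pass_links_fast_chain(self):
        """Pass 1 (tight gate) joins the slow pair; pass 2 (wide) the fast."""
        slow_a = _tracklet(0, [(i * 1.0, 0) for i in range(5)])
        slow_b = _tracklet(1, [(6.0 + i, 0) for i in range(5)], start=6)
        fast_a = _tracklet(2, [(i * 8.0, 50) for i in range(5)])
        fast_b = _tracklet(3, [(48.0 + i * 8, 50) for i in range(5)], start=6)
        params1 = LinkParams(pair_gate_px=5.0, passes=[{}])
        t1 = multi_pass([slow_a, slow_b, fast_a, fast_b], params1)
        assert len(t1) == 3  # only the slow chain joined
        params2 = LinkParams(passes=[{"pair_gate_px": 5.0},
                                     {"pair_gate_px": 30.0}])
        t2 = multi_pass([slow_a, slow_b, fast_a, fast_b], params2)
        assert len(t2) == 2
        # join pass indices recorded
        joined = [t for t in t2 if t.join_passes]
        assert {p for t in joined for p in t.join_passes} == {0, 1}

    def test_conservation_across_passes(self):
        a = _tracklet(0, [(i, 0) for i in range(5)])
        b = _tracklet(1, [(7 + i, 0) for i in range(5)], start=7)
        params = LinkParams(passes=[{}, {"pair_gate_px": 30.0}])
        tracks = multi_pass([a, b], params)
        assert sum(len(t) for t in tracks) == 10


class TestFilterTracks:
    def _track_net(self, tid, net_px):
        return _tracklet(tid, [(0, 0), (net_px / 2, 0), (net_px, 0)])

    def test_length_thresholds(self):
        # nets of 500, 1200, 3000 nm at 100 nm/px
        tracks = [self._track_net(0, 5), self._track_net(1, 12),
                  self._track_net(2, 30)]
        kept_700 = filter_tracks(tracks, min_net_len_nm=700, pixel_size_nm=100)
        kept_1000 = filter_tracks(tracks, min_net_len_nm=1000, pixel_size_nm=100)
        assert len(kept_700) == 2
        assert len(kept_1000) == 2

    def test_min_points(self):
        short = _tracklet(0, [(0, 0), (1, 0)])
        long = _tracklet(1, [(0, 0), (1, 0), (2, 0)])
        assert filter_tracks([short, long], min_points=3) == [long]

    def test_physical_filter_requires_pixel_size(self):
        with pytest.raises(ValueError, match="pixel_size_nm"):
            filter_tracks([self._track_net(0, 5)], min_net_len_nm=700)


class TestPairGateMonotonicity:
    def test_larger_gate_never_fewer_joins(self, rng):
        tracklets = []
        for k in range(8):
            x0 = k * 12.0
            tracklets.append(_tracklet(k, [(x0 + i, 0) for i in range(4)],
                                       start=k * 5))
        counts = []
        for gate in (5.0, 10.0, 20.0, 40.0):
            params = LinkParams(pair_gate_px=gate, pair_gate_frames=10)
            tracks = link_tracklets(tracklets, params)
            counts.append(len(tracklets) - len(tracks))  # joins made
        assert counts == sorted(counts)
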