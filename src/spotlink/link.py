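"""Two-step data association: proximity tracklets, then Bayesian-network
tracklet connectivity.

Step 1 (:func:`form_tracklets`) processes frames sequentially, matching open
tracklets to new detections with the Hungarian algorithm on Euclidean
distance; unmatched detections open new tracklets, tracklets unmatched for
too many frames close, and a length cap keeps tracklets short and reliable.

Step 2 (:func:`link_tracklets`) scores every pair of tracklets that is close
in space and time with a discrete Bayesian network over appearance
(intensity similarity), motion (orientation and speed similarity), location
(end-to-start distance), and temporal evidence (order/overlap and frame
gap).  The posterior probability that the pair belongs to one trajectory,
``P_c = P(CS=True | I, Or, Sp, Od, Ov, G)``, feeds a predecessor→successor
assignment (cost ``1 − P_c``, gate ``1 − score_min``) solved with the
Hungarian algorithm; chains of joined tracklets become tracks.  The process
can be repeated with different gates (multi-pass), e.g. a small distance
first for slow particles and a larger one for fast ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from spotlink.bayesnet import DiscreteBayesNet
from spotlink.config import LinkParams
from spotlink.core import Detection, Track

__all__ = [
    "ConnectivityScore",
    "TrackletPairEvidence",
    "assign",
    "form_tracklets",
    "build_connectivity_net",
    "pair_evidence",
    "score_pair",
    "link_tracklets",
    "multi_pass",
    "filter_tracks",
    "link_detections",
]

log = logging.getLogger(__name__)

_BIG = 1e12


def assign(
    costs: np.ndarray, gate: float = math.inf
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost one-to-one matching among pairs with cost ≤ gate.

    Entities left unmatched are charged the gate value, so a pair is matched
    exactly when doing so lowers the total cost.  Returns matched (row, col)
    pairs plus unmatched row and column indices.
    """
    costs = np.asarray(costs, dtype=float)
    if costs.size == 0:
        return [], list(range(costs.shape[0])), list(range(costs.shape[1]))
    if not np.isfinite(costs).all():
        raise ValueError("costs must be finite")
    n, m = costs.shape
    g = min(gate, _BIG / 4)
    top_left = np.where(costs <= gate, costs, _BIG)
    top_right = np.full((n, n), _BIG)
    np.fill_diagonal(top_right, g)
    bottom_left = np.full((m, m), _BIG)
    np.fill_diagonal(bottom_left, g)
    bottom_right = np.zeros((m, n))
    padded = np.block([[top_left, top_right], [bottom_left, bottom_right]])
    rows, cols = linear_sum_assignment(padded)
    pairs = [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and costs[r, c] <= gate
    ]
    matched_r = {r for r, _ in pairs}
    matched_c = {c for _, c in pairs}
    return (
        pairs,
        [r for r in range(n) if r not in matched_r],
        [c for c in range(m) if c not in matched_c],
    )


@dataclass
class _OpenTracklet:
    detections: list[Detection]
    last_missed: int = 0


def form_tracklets(
    detections_by_frame: list[list[Detection]], params: LinkParams
) -> list[Track]:
    """Frame-sequential proximity linking into short tracklets."""
    open_: list[_OpenTracklet] = []
    closed: list[list[Detection]] = []

    def close(tr: _OpenTracklet) -> None:
        if tr.detections:
            closed.append(tr.detections)

    for dets in detections_by_frame:
        # close tracklets that have been missing too long
        still_open = []
        for tr in open_:
            if tr.last_missed > params.max_missed_frames:
                close(tr)
            else:
                still_open.append(tr)
        open_ = still_open

        if dets and open_:
            last = np.array([[t.detections[-1].x, t.detections[-1].y]
                             for t in open_])
            cur = np.array([[d.x, d.y] for d in dets])
            costs = np.hypot(
                last[:, 0:1] - cur[None, :, 0], last[:, 1:2] - cur[None, :, 1]
            )
            pairs, un_rows, un_cols = assign(costs, params.max_link_dist_px)
        else:
            pairs, un_rows, un_cols = [], list(range(len(open_))), list(
                range(len(dets)))

        next_open: list[_OpenTracklet] = []
        for r, c in pairs:
            tr = open_[r]
            tr.detections.append(dets[c])
            tr.last_missed = 0
            if len(tr.detections) >= params.max_tracklet_len:
                close(tr)  # cap reached: close; a successor starts on the
                # next matching detection
            else:
                next_open.append(tr)
        for r in un_rows:
            open_[r].last_missed += 1
            next_open.append(open_[r])
        for c in un_cols:
            next_open.append(_OpenTracklet(detections=[dets[c]], last_missed=0))
        open_ = next_open

    for tr in open_:
        close(tr)
    closed.sort(key=lambda d: (d[0].frame, d[0].x, d[0].y))
    return [Track(id=i, detections=d) for i, d in enumerate(closed)]


# ---------------------------------------------------------------------------
# Bayesian-network connectivity scoring


@dataclass(frozen=True)
class TrackletPairEvidence:
    """Discretized evidence for one ordered tracklet pair (states 0 = most
    favorable for connectivity; ``None`` = uninformative, left unobserved)."""

    intensity: int
    orientation: int | None
    speed: int | None
    seq: int            # 0 in-order no-overlap, 1 overlap, 2 reversed
    gap: int
    distance: int


@dataclass(frozen=True)
class ConnectivityScore:
    p_c: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_c <= 1.0:
            raise ValueError("P_c must lie in [0, 1]")


def build_connectivity_net(cpts: dict) -> DiscreteBayesNet:
    """Connectivity network: CS → {intensity, orientation, speed, distance,
    gap, seq}; the seq state is derived from the order and overlap parents."""
    net = DiscreteBayesNet()
    pt = float(cpts["prior_true"])
    # state 0 = True so evidence tables index naturally
    net.add_node("CS", 2, cpt=[pt, 1.0 - pt])
    for name in ("intensity", "orientation", "speed", "distance", "gap", "seq"):
        tab = cpts[name]
        net.add_node(name, len(tab["true"]), parents=["CS"],
                     cpt=[tab["true"], tab["false"]])
    return net


def _terminal_segment(dets: list[Detection], end: str) -> tuple[float, float] | None:
    """(heading_rad, speed_px_per_frame) of the terminal segment, or None.

    The mean velocity over up to the last (first) three steps is used, which
    suppresses localization noise relative to a single step."""
    if len(dets) < 2:
        return None
    span = min(3, len(dets) - 1)
    a, b = (dets[0], dets[span]) if end == "head" else (dets[-1 - span], dets[-1])
    dt = b.frame - a.frame
    dx, dy = (b.x - a.x) / dt, (b.y - a.y) / dt
    return math.atan2(-dy, dx), math.hypot(dx, dy)


def _discretize(value: float, cuts: list[float]) -> int:
    return int(np.searchsorted(np.asarray(cuts, dtype=float), value, side="right"))


def pair_evidence(
    a: Track, b: Track, params: LinkParams
) -> TrackletPairEvidence | None:
    """Evidence for the ordered pair (a before b), or None if out of gate."""
    gap = b.start_frame - a.end_frame
    if gap > params.pair_gate_frames:
        return None
    if gap < -params.overlap_tolerance_frames:
        return None
    pa, pb = a.detections[-1], b.detections[0]
    dist = math.hypot(pb.x - pa.x, pb.y - pa.y)
    if dist > params.pair_gate_px:
        return None
    th = params.thresholds

    ia, ib = pa.roi_mean, pb.roi_mean
    if min(ia, ib) <= 0:
        intensity = 0 if max(ia, ib) <= 0 else 2
    else:
        intensity = _discretize(max(ia, ib) / min(ia, ib), th["intensity_ratio"])

    seg_a = _terminal_segment(a.detections, "tail")
    seg_b = _terminal_segment(b.detections, "head")
    floor = float(th.get("speed_floor_px", 1.0))  # localization-noise scale
    if seg_a is None or seg_b is None:
        orientation = speed = None
    else:
        sa, sb = seg_a[1], seg_b[1]
        if min(sa, sb) < floor:
            # a sub-noise step has no meaningful heading
            orientation = None
        else:
            dang = abs(math.degrees(seg_a[0] - seg_b[0])) % 360.0
            if dang > 180.0:
                dang = 360.0 - dang
            orientation = _discretize(dang, th["angle_deg"])
        # additive floor keeps the ratio well-behaved for near-stationary ends
        speed = _discretize((max(sa, sb) + floor) / (min(sa, sb) + floor),
                            th["speed_ratio"])

    in_order = b.start_frame > a.start_frame and b.end_frame > a.end_frame
    overlap = gap <= 0
    seq = 2 if not in_order else (1 if overlap else 0)
    gap_state = _discretize(float(max(gap, 0)), th["gap_frames"])
    dist_state = _discretize(dist / params.pair_gate_px, th["distance_frac"])
    return TrackletPairEvidence(
        intensity=intensity, orientation=orientation, speed=speed,
        seq=seq, gap=gap_state, distance=dist_state,
    )


def score_pair(
    a: Track, b: Track, params: LinkParams, net: DiscreteBayesNet | None = None
) -> ConnectivityScore | None:
    """Connectivity score P_c for the ordered pair, or None when the pair is
    not comparable (outside the space/time gate)."""
    ev = pair_evidence(a, b, params)
    if ev is None:
        return None
    if net is None:
        net = build_connectivity_net(params.cpts)
    observed = {"seq": ev.seq, "gap": ev.gap, "distance": ev.distance,
                "intensity": ev.intensity}
    if ev.orientation is not None:
        observed["orientation"] = ev.orientation
    if ev.speed is not None:
        observed["speed"] = ev.speed
    post = net.posterior("CS", observed)
    return ConnectivityScore(p_c=float(post[0]))


def _scored_pairs(
    tracklets: list[Track], params: LinkParams
) -> dict[tuple[int, int], float]:
    """Connectivity cost (1 − P_c) for every joinable in-gate tracklet pair.

    Candidate successors are found through a frame index of tracklet heads,
    so the cost is linear in the number of in-gate pairs rather than
    quadratic in the number of tracklets."""
    net = build_connectivity_net(params.cpts)
    heads: dict[int, list[int]] = {}
    for j, t in enumerate(tracklets):
        heads.setdefault(t.start_frame, []).append(j)
    costs: dict[tuple[int, int], float] = {}
    for i, a in enumerate(tracklets):
        tail = a.detections[-1]
        # joins must advance time so chains stay acyclic and frames
        # strictly increase after concatenation
        for f in range(a.end_frame + 1, a.end_frame + params.pair_gate_frames + 1):
            for j in heads.get(f, ()):
                if i == j:
                    continue
                b = tracklets[j]
                head = b.detections[0]
                if math.hypot(head.x - tail.x, head.y - tail.y) > params.pair_gate_px:
                    continue
                score = score_pair(a, b, params, net)
                if score is not None:
                    costs[(i, j)] = 1.0 - score.p_c
    return costs


def _assign_sparse(
    costs: dict[tuple[int, int], float], n: int, gate: float
) -> list[tuple[int, int]]:
    """Gated minimum-cost one-to-one matching from a sparse cost dict.

    Equivalent to :func:`assign` on the dense matrix (entities left
    unmatched are charged the gate), built as a square sparse problem so
    large, mostly-empty instances stay tractable."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import min_weight_full_bipartite_matching

    admissible = {k: v for k, v in costs.items() if v <= gate}
    if not admissible:
        return []
    eps = 1e-9  # csgraph treats exact zeros as missing edges
    rows, cols, data = [], [], []
    for (i, j), c in admissible.items():
        rows.append(i)
        cols.append(j)
        data.append(c + eps)
        # when i and j are matched, their dummies pair with each other
        rows.append(n + j)
        cols.append(n + i)
        data.append(eps)
    for i in range(n):
        rows.append(i)
        cols.append(n + i)
        data.append(gate + eps)   # row i unmatched
        rows.append(n + i)
        cols.append(i)
        data.append(gate + eps)   # col i unmatched
    mat = coo_matrix((data, (rows, cols)), shape=(2 * n, 2 * n)).tocsr()
    r, c = min_weight_full_bipartite_matching(mat)
    return [
        (int(i), int(j))
        for i, j in zip(r, c)
        if i < n and j < n and (i, j) in admissible
    ]


def link_tracklets(
    tracklets: list[Track], params: LinkParams, pass_index: int = 0
) -> list[Track]:
    """Assemble tracklets into tracks via Hungarian predecessor→successor
    assignment on connectivity scores.  Conserves every detection."""
    n = len(tracklets)
    if n == 0:
        return []
    costs = _scored_pairs(tracklets, params)
    pairs = _assign_sparse(costs, n, gate=1.0 - params.score_min)
    successor = dict(pairs)
    has_pred = {j for _, j in pairs}
    tracks: list[Track] = []
    for i, t in enumerate(tracklets):
        if i in has_pred:
            continue
        dets = list(t.detections)
        passes = list(t.join_passes)
        j = i
        seen = {i}
        while j in successor:
            j = successor[j]
            assert j not in seen, "cyclic tracklet chain"
            seen.add(j)
            nxt = tracklets[j]
            assert nxt.start_frame > dets[-1].frame
            dets.extend(nxt.detections)
            passes.extend(nxt.join_passes)
            passes.append(pass_index)
        tracks.append(Track(id=len(tracks), detections=dets, join_passes=passes))
    return tracks


def multi_pass(tracklets: list[Track], params: LinkParams) -> list[Track]:
    """Run track-linking once per configured pass, re-linking the current
    track set each time (typically with a growing distance gate)."""
    passes = params.passes or [{}]
    tracks = tracklets
    for k, overrides in enumerate(passes):
        p = replace(params, **overrides) if overrides else params
        tracks = link_tracklets(tracks, p, pass_index=k)
    return tracks


def filter_tracks(
    tracks: list[Track],
    min_points: int = 1,
    min_net_len_nm: float = 0.0,
    pixel_size_nm: float | None = None,
) -> list[Track]:
    """Keep tracks with enough points and a long enough net length."""
    if min_net_len_nm > 0 and pixel_size_nm is None:
        raise ValueError("pixel_size_nm required for a physical length filter")
    out = []
    for t in tracks:
        if len(t) < min_points:
            continue
        if min_net_len_nm > 0 and t.net_length_px() * pixel_size_nm < min_net_len_nm:
            continue
        out.append(t)
    return out


def link_detections(
    detections_by_frame: list[list[Detection]], params: LinkParams
) -> list[Track]:
    """Full linking: tracklets, then (multi-pass) Bayesian-network assembly."""
    tracklets = form_tracklets(detections_by_frame, params)
    log.debug("%d tracklets formed", len(tracklets))
    return multi_pass(tracklets, params)
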