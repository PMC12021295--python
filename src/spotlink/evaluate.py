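"""Tracking-performance metrics against ground truth.

Tracks are paired one-to-one by minimizing a gated point-wise distance: for
a ground-truth track θ_g and an estimated track θ_e,

    d(θ_g, θ_e) = Σ_{frames in union} min(‖p_g − p_e‖, ε),

with the penalty ε charged for every frame where either track lacks a point.
An unpaired ground-truth track contributes its empty-match penalty
``n_points·ε``.  From the optimal pairing:

* α = 1 − D(gt, est) / D(gt, ∅) — linking accuracy, ignoring spurious
  (unmatched estimated) tracks; 1 is perfect;
* β = (D(gt, ∅) − D(gt, est)) / (D(gt, ∅) + D(spurious, ∅)) — like α but
  penalized by spurious tracks, so 0 ≤ β ≤ α;
* JSC — Jaccard coefficient over points: TP/(TP+FN+FP), a point matching
  within ε of its paired partner being a TP;
* JSC_θ — Jaccard coefficient over whole tracks:
  paired/(paired + unpaired gt + spurious);
* RMSE — root mean square distance over matched point pairs (px);
* γ — fraction of ground-truth tracks "detected": paired with at least
  ``gamma_min_cover`` of their points matched within ε.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from spotlink.config import EvaluateParams
from spotlink.core import Track, TrackSet
from spotlink.io import read_tracks
from spotlink.link import assign

__all__ = [
    "TrackPairing",
    "EvaluationReport",
    "track_distance",
    "pair_tracks",
    "compute_metrics",
    "evaluate_run",
]

log = logging.getLogger(__name__)
_BIG = 1e12


def track_distance(
    gt: Track, est: Track, epsilon_px: float
) -> tuple[float, int, float]:
    """Gated distance over the frame union.

    Returns ``(distance, n_matched, sum_sq_matched)`` where ``n_matched``
    counts frames with both points within ε and ``sum_sq_matched`` their
    squared-distance sum.
    """
    g = {d.frame: (d.x, d.y) for d in gt}
    e = {d.frame: (d.x, d.y) for d in est}
    total = 0.0
    matched = 0
    ssq = 0.0
    for f in set(g) | set(e):
        if f in g and f in e:
            dist = math.hypot(g[f][0] - e[f][0], g[f][1] - e[f][1])
            if dist < epsilon_px:
                matched += 1
                ssq += dist * dist
            total += min(dist, epsilon_px)
        else:
            total += epsilon_px
    return total, matched, ssq


@dataclass
class TrackPairing:
    pairs: list[tuple[int, int]]            # (gt index, est index)
    pair_stats: dict[tuple[int, int], tuple[float, int, float]]
    unpaired_gt: list[int]
    spurious_est: list[int]
    gt: TrackSet
    est: TrackSet
    params: EvaluateParams


def _candidate(gt: Track, est: Track, radius: float) -> bool:
    if est.start_frame > gt.end_frame or gt.start_frame > est.end_frame:
        return False
    cg = gt.xy.mean(axis=0)
    ce = est.xy.mean(axis=0)
    return float(np.hypot(*(cg - ce))) <= radius


def pair_tracks(
    gt: TrackSet, est: TrackSet, params: EvaluateParams | None = None
) -> TrackPairing:
    """Optimal one-to-one ground-truth↔estimate pairing.

    Only pairs overlapping in time with centroids within
    ``candidate_radius_px`` are scored.  Pairs in which no point ever falls
    within ε are dissolved into unpaired/spurious.
    """
    params = params or EvaluateParams()
    eps = params.epsilon_px
    n_g, n_e = len(gt.tracks), len(est.tracks)
    stats: dict[tuple[int, int], tuple[float, int, float]] = {}
    costs = np.full((n_g, n_e), _BIG)
    for i, g in enumerate(gt.tracks):
        for j, e in enumerate(est.tracks):
            if not _candidate(g, e, params.candidate_radius_px):
                continue
            d, m, ssq = track_distance(g, e, eps)
            stats[(i, j)] = (d, m, ssq)
            costs[i, j] = d
    empty_penalty = np.array([len(g) * eps for g in gt.tracks])
    # pad: unmatched gt pays its empty-match penalty, unmatched est is free
    top_right = np.full((n_g, n_g), _BIG)
    np.fill_diagonal(top_right, empty_penalty)
    bottom_left = np.zeros((n_e, n_e)) + _BIG
    np.fill_diagonal(bottom_left, 0.0)
    padded = np.block(
        [[costs, top_right],
         [bottom_left, np.zeros((n_e, n_g))]]
    ) if n_g and n_e else None
    pairs: list[tuple[int, int]] = []
    if padded is not None:
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(padded)
        for r, c in zip(rows, cols):
            if r < n_g and c < n_e and (r, c) in stats:
                if stats[(r, c)][1] > 0:     # at least one point within ε
                    pairs.append((r, c))
    paired_g = {i for i, _ in pairs}
    paired_e = {j for _, j in pairs}
    return TrackPairing(
        pairs=pairs,
        pair_stats=stats,
        unpaired_gt=[i for i in range(n_g) if i not in paired_g],
        spurious_est=[j for j in range(n_e) if j not in paired_e],
        gt=gt,
        est=est,
        params=params,
    )


@dataclass
class EvaluationReport:
    alpha: float
    beta: float
    jsc: float
    jsc_theta: float
    rmse_px: float
    gamma: float
    n_gt_tracks: int = 0
    n_est_tracks: int = 0
    n_paired: int = 0
    n_spurious: int = 0
    tp_points: int = 0
    fn_points: int = 0
    fp_points: int = 0
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(**d)


def compute_metrics(
    pairing: TrackPairing, params: EvaluateParams | None = None
) -> EvaluationReport:
    """Compute α, β, JSC, JSC_θ, RMSE and γ from a track pairing."""
    params = params or pairing.params
    eps = params.epsilon_px
    gt, est = pairing.gt, pairing.est
    if not gt.tracks:
        raise ValueError("empty ground truth: metrics undefined")
    d_gt_empty = sum(len(g) * eps for g in gt.tracks)
    d_total = 0.0
    tp = 0
    ssq = 0.0
    detected = 0
    for (i, j) in pairing.pairs:
        d, m, s = pairing.pair_stats[(i, j)]
        d_total += d
        tp += m
        ssq += s
        if m / len(gt.tracks[i]) >= params.gamma_min_cover:
            detected += 1
    d_total += sum(len(gt.tracks[i]) * eps for i in pairing.unpaired_gt)
    d_spurious = sum(len(est.tracks[j]) * eps for j in pairing.spurious_est)

    n_gt_points = sum(len(g) for g in gt.tracks)
    n_est_points = sum(len(e) for e in est.tracks)
    fn = n_gt_points - tp
    fp = n_est_points - tp

    alpha = 1.0 - d_total / d_gt_empty
    beta = (d_gt_empty - d_total) / (d_gt_empty + d_spurious)
    jsc = tp / (tp + fn + fp) if tp + fn + fp else 0.0
    n_paired = len(pairing.pairs)
    jsc_theta = n_paired / (
        n_paired + len(pairing.unpaired_gt) + len(pairing.spurious_est)
    ) if (n_paired + len(pairing.unpaired_gt) + len(pairing.spurious_est)) else 0.0
    rmse = math.sqrt(ssq / tp) if tp else math.nan
    gamma = detected / len(gt.tracks)
    return EvaluationReport(
        alpha=alpha,
        beta=beta,
        jsc=jsc,
        jsc_theta=jsc_theta,
        rmse_px=rmse,
        gamma=gamma,
        n_gt_tracks=len(gt.tracks),
        n_est_tracks=len(est.tracks),
        n_paired=n_paired,
        n_spurious=len(pairing.spurious_est),
        tp_points=tp,
        fn_points=fn,
        fp_points=fp,
        params={"epsilon_px": eps, "gamma_min_cover": params.gamma_min_cover},
    )


def evaluate_run(
    gt_path: str | Path,
    est_path: str | Path,
    params: EvaluateParams | None = None,
    out_path: str | Path | None = None,
) -> EvaluationReport:
    """Load two track files, pair them and write a metric report."""
    gt = read_tracks(gt_path)
    est = read_tracks(est_path)
    params = params or EvaluateParams()

    def frame_range(ts: TrackSet) -> tuple[int, int]:
        return (
            min((t.start_frame for t in ts), default=0),
            max((t.end_frame for t in ts), default=0),
        )

    rg, re = frame_range(gt), frame_range(est)
    if rg != re:
        log.warning(
            "frame ranges differ (gt %s vs est %s); evaluating on overlap", rg, re
        )
    report = compute_metrics(pair_tracks(gt, est, params), params)
    if out_path is not None:
        report.save(out_path)
    return report
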