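"""Per-track quantitative measures and directional statistics.

For a track with detections p_1..p_N at pixel size ``s`` (nm) and frame
interval ``t`` (s):

* total distance   d_total = Σ ‖p_{i+1} − p_i‖ — the entire path length;
* net distance     d_net   = ‖p_N − p_1‖;
* maximum distance d_max   = max_i ‖p_i − p_1‖ (an option measures the
  largest distance between any two points instead);
* trajectory time  t_traj  = (last_frame − first_frame) · t — frames where
  the detection was missed still count toward elapsed time;
* net orientation  θ_net from p_1 → p_N, measured so that "up" in the image
  (decreasing row) is 90°;
* normalized brightness b̄ = mean over detections of (mean ROI intensity /
  brightest pixel of the sequence);
* curvilinear speed v = d_total / t_traj, straight-line speed
  v_line = d_net / t_traj;
* moving segments from a rolling-window MSD exponent (directed motion has
  exponent ≈ 2, confined/paused ≈ 0–1), and the maximum curvilinear speed
  over a sliding time window fully inside moving segments.

Directional statistics classify tracks by net heading into a 90° cone around
a user-supplied tissue axis (apical/leading), the opposite cone
(basal/trailing) and the two lateral quadrants, bin headings into 10° polar
histograms normalized to tracks per minute, and project net displacement
onto the axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from spotlink.config import TrajectoryParams
from spotlink.core import ImageSequence, MissingMetadataError, Track

__all__ = [
    "TrajectoryMeasures",
    "AxisFrame",
    "PolarHistogram",
    "measures",
    "segment_motion",
    "max_segment_speed",
    "classify_direction",
    "polar_histogram",
    "axis_displacement",
    "framewise_pearson",
]


@dataclass(frozen=True)
class TrajectoryMeasures:
    track_id: int
    first_frame: int
    last_frame: int
    n_points: int
    d_total_um: float
    d_net_um: float
    d_max_um: float
    t_traj_s: float
    theta_net_deg: float
    b_mean: float
    v_curvilinear_um_s: float
    v_line_um_s: float
    v_max_segment_um_s: float = math.nan
    n_moving_segments: int = -1          # -1 = not segmented
    t_avg_moving_s: float = math.nan


@dataclass(frozen=True)
class AxisFrame:
    """Tissue axes in analysis coordinates (degrees, image convention:
    0° = +x, 90° = up)."""

    apical_angle_deg: float = 90.0
    leading_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        for a in (self.apical_angle_deg, self.leading_angle_deg):
            if not 0.0 <= a < 360.0:
                raise ValueError("angles must lie in [0, 360)")


def _theta_deg(dx: float, dy: float) -> float:
    """Heading in degrees with image-up at 90° (y is the row index)."""
    return math.degrees(math.atan2(-dy, dx)) % 360.0


def measures(
    track: Track,
    frame_interval_s: float | None = None,
    pixel_size_nm: float | None = None,
    b_max: float | None = None,
    segment_params: TrajectoryParams | None = None,
) -> TrajectoryMeasures:
    """Compute the full measure set for one track.

    ``b_max`` is the brightest pixel value of the image sequence, used to
    normalize the mean ROI brightness; omit it to report raw brightness.
    When ``segment_params`` is given, moving segments and the windowed
    maximum speed are included.
    """
    if len(track) < 2:
        raise ValueError("measures need at least 2 detections")
    if frame_interval_s is None or pixel_size_nm is None:
        raise MissingMetadataError("frame_interval_s and pixel_size_nm required")
    um = pixel_size_nm / 1000.0
    p = track.xy * um
    steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    d_total = float(steps.sum())
    d_net = float(np.linalg.norm(p[-1] - p[0]))
    d_max = float(np.max(np.linalg.norm(p - p[0], axis=1)))
    t_traj = (track.end_frame - track.start_frame) * frame_interval_s
    theta = _theta_deg(p[-1, 0] - p[0, 0], p[-1, 1] - p[0, 1])
    roi_means = np.array([d.roi_mean for d in track])
    b_mean = float(np.mean(roi_means / b_max)) if b_max else float(roi_means.mean())

    v_max = math.nan
    k = -1
    t_avg = math.nan
    if segment_params is not None:
        labels, segments = segment_motion(track, segment_params)
        if labels is not None:
            k = len(segments)
            if k > 0:
                seg_times = [
                    (track.detections[j].frame - track.detections[i].frame)
                    * frame_interval_s
                    for i, j in segments
                ]
                t_avg = float(np.mean(seg_times))
            vm = max_segment_speed(
                track, segments, segment_params.speed_window_s,
                frame_interval_s, pixel_size_nm,
            )
            v_max = vm if vm is not None else math.nan

    return TrajectoryMeasures(
        track_id=track.id,
        first_frame=track.start_frame,
        last_frame=track.end_frame,
        n_points=len(track),
        d_total_um=d_total,
        d_net_um=d_net,
        d_max_um=d_max,
        t_traj_s=float(t_traj),
        theta_net_deg=theta,
        b_mean=b_mean,
        v_curvilinear_um_s=d_total / t_traj,
        v_line_um_s=d_net / t_traj,
        v_max_segment_um_s=v_max,
        n_moving_segments=k,
        t_avg_moving_s=t_avg,
    )


def max_distance_pairwise(track: Track, pixel_size_nm: float) -> float:
    """Option: largest distance between ANY two track points (µm)."""
    p = track.xy * (pixel_size_nm / 1000.0)
    d = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
    return float(d.max())


def _msd_exponent(p: np.ndarray, n_lags: int) -> float:
    """Log-log slope of MSD over lags 1..n_lags inside one window."""
    lags = range(1, min(n_lags, len(p) - 1) + 1)
    msd, ls = [], []
    for lag in lags:
        disp = p[lag:] - p[:-lag]
        m = float(np.mean(np.sum(disp**2, axis=1)))
        if m > 1e-12:
            msd.append(m)
            ls.append(lag)
    if len(msd) < 2:
        return 0.0   # (near-)stationary window
    slope = np.polyfit(np.log(ls), np.log(msd), 1)[0]
    return float(slope)


def segment_motion(
    track: Track, params: TrajectoryParams | None = None
) -> tuple[np.ndarray | None, list[tuple[int, int]]]:
    """Label each point moving/paused from a rolling-window MSD exponent.

    Returns ``(labels, segments)`` where ``labels`` is a boolean array per
    detection and ``segments`` a list of (start_idx, end_idx) index pairs of
    contiguous moving runs.  Tracks shorter than the MSD window cannot be
    segmented and return ``(None, [])``.
    """
    params = params or TrajectoryParams()
    w = params.msd_window
    n = len(track)
    if n < w:
        return None, []
    p = track.xy
    exponents = np.empty(n)
    half = w // 2
    for i in range(n):
        lo = max(0, min(i - half, n - w))
        exponents[i] = _msd_exponent(p[lo : lo + w], params.msd_lags)
    labels = exponents >= params.msd_alpha_moving
    segments: list[tuple[int, int]] = []
    start = None
    for i, lab in enumerate(labels):
        if lab and start is None:
            start = i
        elif not lab and start is not None:
            segments.append((start, i - 1))
            start = None
    if start is not None:
        segments.append((start, n - 1))
    # a segment needs at least one step
    segments = [(a, b) for a, b in segments if b > a]
    return labels, segments


def max_segment_speed(
    track: Track,
    segments: list[tuple[int, int]],
    window_s: float,
    frame_interval_s: float,
    pixel_size_nm: float,
) -> float | None:
    """Maximum curvilinear speed over a sliding time window fully inside a
    moving segment (µm/s), or None when no segment is long enough."""
    if window_s < frame_interval_s:
        raise ValueError("window_s must be at least one frame interval")
    w = max(1, round(window_s / frame_interval_s))  # window in frame intervals
    um = pixel_size_nm / 1000.0
    best = None
    frames = track.frames
    p = track.xy * um
    for a, b in segments:
        for i in range(a, b + 1):
            # find j with frames[j] - frames[i] == w (gaps allowed inside)
            j = i
            while j <= b and frames[j] - frames[i] < w:
                j += 1
            if j > b or frames[j] - frames[i] != w:
                continue
            path = float(
                np.sum(np.linalg.norm(np.diff(p[i : j + 1], axis=0), axis=1))
            )
            speed = path / (w * frame_interval_s)
            if best is None or speed > best:
                best = speed
    return best


def _angular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def classify_direction(
    theta_net_deg: float, axis: AxisFrame, planar: bool = False
) -> str:
    """Quadrant classification of a net heading.

    Within 45° of the apical (or leading) axis → ``apical``/``leading``;
    within 45° of the opposite direction → ``basal``/``trailing``; otherwise
    the two 90° side quadrants → ``lateral``/``perpendicular``.  Ties at
    exactly 45° go to the axial class.
    """
    ref = axis.leading_angle_deg if planar else axis.apical_angle_deg
    d = _angular_distance(theta_net_deg, ref)
    if d <= 45.0:
        return "leading" if planar else "apical"
    if d >= 135.0:
        return "trailing" if planar else "basal"
    return "perpendicular" if planar else "lateral"


@dataclass
class PolarHistogram:
    """10° heading histogram of tracks with a minimum net displacement."""

    bin_edges_deg: np.ndarray        # 37 edges over [0, 360]
    counts: np.ndarray               # tracks per bin
    counts_per_min: np.ndarray
    net_distance_um: np.ndarray      # summed net distance per bin
    duration_min: float
    n_included: int
    n_excluded: int


def polar_histogram(
    theta_net_deg: np.ndarray,
    d_net_um: np.ndarray,
    duration_min: float,
    min_net_um: float = 1.0,
) -> PolarHistogram:
    """Bin net headings of tracks traveling ≥ ``min_net_um`` into 36 bins of
    10°, with counts normalized to tracks per minute."""
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    theta = np.asarray(theta_net_deg, dtype=float) % 360.0
    d_net = np.asarray(d_net_um, dtype=float)
    keep = d_net >= min_net_um
    edges = np.arange(0.0, 361.0, 10.0)
    idx = np.minimum((theta[keep] // 10).astype(int), 35)
    counts = np.bincount(idx, minlength=36).astype(float)
    sums = np.bincount(idx, weights=d_net[keep], minlength=36)
    return PolarHistogram(
        bin_edges_deg=edges,
        counts=counts,
        counts_per_min=counts / duration_min,
        net_distance_um=sums,
        duration_min=duration_min,
        n_included=int(keep.sum()),
        n_excluded=int((~keep).sum()),
    )


def axis_displacement(
    track: Track, axis: AxisFrame, pixel_size_nm: float, planar: bool = False
) -> float:
    """Signed net displacement (µm) along the apical (or leading) axis;
    positive toward apical/leading."""
    um = pixel_size_nm / 1000.0
    p = track.xy
    dx = (p[-1, 0] - p[0, 0]) * um
    dy = (p[-1, 1] - p[0, 1]) * um
    ref = math.radians(
        axis.leading_angle_deg if planar else axis.apical_angle_deg
    )
    # unit vector of the axis in (x, y-row) image coordinates
    ux, uy = math.cos(ref), -math.sin(ref)
    return float(dx * ux + dy * uy)


def framewise_pearson(
    seq_a: ImageSequence,
    seq_b: ImageSequence,
    reference: str = "first",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame Pearson correlation of two same-shape sequences.

    Returns ``(r, normalized)`` where ``normalized`` is the delta series
    anchored at the reference time point (first frame by default, last frame
    optionally) and divided by K, the maximum delta, so the peak change is 1.
    Frames with zero variance get NaN.
    """
    if seq_a.shape != seq_b.shape:
        raise ValueError("sequences must share shape")
    r = np.empty(seq_a.n_frames)
    for t in range(seq_a.n_frames):
        a = seq_a.frames[t].ravel().astype(float)
        b = seq_b.frames[t].ravel().astype(float)
        if a.std() == 0 or b.std() == 0:
            r[t] = np.nan
            continue
        r[t] = float(np.corrcoef(a, b)[0, 1])
    anchor = r[0] if reference == "first" else r[-1]
    delta = r - anchor
    k = np.nanmax(np.abs(delta))
    normalized = delta / k if k > 0 else delta
    return r, normalized
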