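"""Synthetic time-lapse movies with known ground-truth tracks.

The generator emulates the standard evaluation scenario for sub-resolution
particle trackers: moving diffraction-limited spots rendered as isotropic
Gaussians on a constant background, corrupted by per-pixel Poisson noise at a
requested peak SNR, at three density presets (low/middle/high).  On top of
that it reproduces the nuisance structure of real secretory-pathway movies:
bright, larger, immobile Golgi-like distractor blobs and diffuse background.

SNR convention: ``snr = A / sqrt(A + b)`` where ``A`` is the spot peak
amplitude above the mean background ``b`` — the shot-noise-limited SNR at the
brightest pixel of the spot.  Given ``b`` and ``snr`` the amplitude is
``A = (snr^2 + snr*sqrt(snr^2 + 4 b)) / 2``.

Motion models per particle:

* ``directed`` — constant speed and heading, reflecting off an interior
  margin so spots stay in the usable field of view;
* ``brownian`` — isotropic Gaussian steps;
* ``switching`` — directed runs interrupted by pauses, with geometric dwell
  times (defaults: mean 10 frames moving, 5 paused), which produces the
  moving-segment structure the trajectory analytics measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from spotlink.config import ScenarioParams
from spotlink.core import Detection, ImageSequence, Track, TrackSet

__all__ = [
    "GroundTruth",
    "LabeledPatches",
    "amplitude_for_snr",
    "density_particle_count",
    "render_training_patches",
    "simulate",
]

DENSITY_PRESETS = {"low": 10, "middle": 50, "high": 100}  # particles per 512×512


def amplitude_for_snr(snr: float, background: float) -> float:
    """Peak amplitude A solving snr = A / sqrt(A + background)."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return 0.5 * (snr**2 + snr * math.sqrt(snr**2 + 4.0 * background))


def density_particle_count(density: str, H: int, W: int) -> int:
    if density not in DENSITY_PRESETS:
        raise ValueError(
            f"unknown density preset {density!r}; H/W plus one of "
            f"{sorted(DENSITY_PRESETS)} required"
        )
    return max(1, round(DENSITY_PRESETS[density] * (H * W) / (512 * 512)))


@dataclass
class GroundTruth:
    """True particle positions (noiseless spot centers) and motion labels."""

    tracks: TrackSet
    moving: dict[int, np.ndarray] = field(default_factory=dict)  # per-frame bool
    distractors: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))
    # distractors rows: (x, y, sigma_px, amplitude)


@dataclass
class LabeledPatches:
    """Training patches for the spot/background classifier."""

    patches: np.ndarray   # (n, roi, roi) float
    labels: np.ndarray    # (n,) int, 1 = spot
    roi_px: int


def _gauss_spot(H: int, W: int, x0: float, y0: float, sigma: float,
                amp: float) -> np.ndarray:
    """Isotropic Gaussian of peak ``amp`` at subpixel center, truncated at 5σ."""
    r = int(math.ceil(5 * sigma))
    x_lo, x_hi = max(0, int(x0) - r), min(W, int(x0) + r + 1)
    y_lo, y_hi = max(0, int(y0) - r), min(H, int(y0) + r + 1)
    out = np.zeros((H, W))
    if x_lo >= x_hi or y_lo >= y_hi:
        return out
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    out[y_lo:y_hi, x_lo:x_hi] = amp * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2)
    )
    return out


def _reflect(pos: float, vel: float, lo: float, hi: float) -> tuple[float, float]:
    while pos < lo or pos > hi:
        if pos < lo:
            pos = 2 * lo - pos
        else:
            pos = 2 * hi - pos
        vel = -vel
    return pos, vel


def _simulate_paths(p: ScenarioParams, n: int, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Return positions (n, T, 2) and moving labels (n, T)."""
    lo_x, hi_x = p.margin_px, p.W - 1 - p.margin_px
    lo_y, hi_y = p.margin_px, p.H - 1 - p.margin_px
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("frame too small for the configured margin")
    if p.motion in ("directed", "switching"):
        span = min(hi_x - lo_x, hi_y - lo_y)
        if p.speed_px * 2 > 2 * span:
            raise ValueError(
                f"speed {p.speed_px} px/frame exits the usable field in < 2 frames"
            )
    pos = np.empty((n, p.T, 2))
    moving = np.zeros((n, p.T), dtype=bool)
    for i in range(n):
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        heading = (
            math.radians(p.heading_deg)
            if p.heading_deg is not None
            else rng.uniform(0, 2 * math.pi)
        )
        # image convention: heading 0° = +x, 90° = up (decreasing row)
        vx = p.speed_px * math.cos(heading)
        vy = -p.speed_px * math.sin(heading)
        if p.motion == "switching":
            state = rng.random() < p.dwell_moving / (p.dwell_moving + p.dwell_paused)
            dwell = rng.geometric(1.0 / (p.dwell_moving if state else p.dwell_paused))
        for t in range(p.T):
            pos[i, t] = (x, y)
            if p.motion == "directed":
                moving[i, t] = True
                x, vx = _reflect(x + vx, vx, lo_x, hi_x)
                y, vy = _reflect(y + vy, vy, lo_y, hi_y)
            elif p.motion == "brownian":
                step = rng.normal(0.0, p.diffusion_sd_px, size=2)
                x, _ = _reflect(x + step[0], 0.0, lo_x, hi_x)
                y, _ = _reflect(y + step[1], 0.0, lo_y, hi_y)
            else:  # switching
                moving[i, t] = state
                if state:
                    x, vx = _reflect(x + vx, vx, lo_x, hi_x)
                    y, vy = _reflect(y + vy, vy, lo_y, hi_y)
                dwell -= 1
                if dwell <= 0:
                    state = not state
                    dwell = rng.geometric(
                        1.0 / (p.dwell_moving if state else p.dwell_paused)
                    )
                    if state:
                        heading = rng.uniform(0, 2 * math.pi)
                        vx = p.speed_px * math.cos(heading)
                        vy = -p.speed_px * math.sin(heading)
    return pos, moving


def simulate(params: ScenarioParams) -> tuple[ImageSequence, GroundTruth]:
    """Render a movie and its ground truth; identical params+seed give
    identical output."""
    p = params
    if p.T < 2:
        raise ValueError("T must be ≥ 2")
    if p.snr <= 0 or p.psf_sigma_px <= 0:
        raise ValueError("snr and psf_sigma_px must be positive")
    if p.motion not in ("directed", "brownian", "switching"):
        raise ValueError(f"unknown motion model {p.motion!r}")
    n = (
        int(p.n_particles)
        if p.n_particles is not None
        else density_particle_count(p.density, p.H, p.W)
    )
    rng = np.random.default_rng(p.seed)
    amp = amplitude_for_snr(p.snr, p.background_level)

    # static distractors: larger, brighter, immobile Golgi-like blobs
    distractors = np.empty((p.n_distractors, 4))
    for j in range(p.n_distractors):
        distractors[j] = (
            rng.uniform(0, p.W - 1),
            rng.uniform(0, p.H - 1),
            rng.uniform(3.0, 6.0),
            amp * rng.uniform(3.0, 10.0),
        )
    static = np.full((p.H, p.W), float(p.background_level))
    for x0, y0, sig, a in distractors:
        static += _gauss_spot(p.H, p.W, x0, y0, sig, a)

    pos, moving = _simulate_paths(p, n, rng) if n > 0 else (
        np.empty((0, p.T, 2)), np.zeros((0, p.T), dtype=bool))

    frames = np.empty((p.T, p.H, p.W), dtype=np.uint16)
    for t in range(p.T):
        clean = static.copy()
        for i in range(n):
            clean += _gauss_spot(p.H, p.W, pos[i, t, 0], pos[i, t, 1],
                                 p.psf_sigma_px, amp)
        noisy = rng.poisson(clean)
        frames[t] = np.clip(noisy, 0, 65535).astype(np.uint16)

    seq = ImageSequence(
        frames=frames,
        pixel_size_nm=p.pixel_size_nm,
        frame_interval_s=p.frame_interval_s,
        bit_depth=16,
    )
    tracks = [
        Track(
            id=i,
            detections=[
                Detection(frame=t, x=float(pos[i, t, 0]), y=float(pos[i, t, 1]))
                for t in range(p.T)
            ],
        )
        for i in range(n)
    ]
    gt = GroundTruth(
        tracks=TrackSet(
            tracks=tracks,
            source="synthetic",
            pixel_size_nm=p.pixel_size_nm,
            frame_interval_s=p.frame_interval_s,
        ),
        moving={i: moving[i].copy() for i in range(n)},
        distractors=distractors,
    )
    return seq, gt


def render_training_patches(
    params: ScenarioParams, n_pos: int, n_neg: int, roi_px: int = 16,
    n_movies: int = 3,
) -> LabeledPatches:
    """Cut labeled classifier patches out of simulated movies.

    Positives are centered (±1 px jitter) on true spots; negatives are drawn
    from plain background, distractor interiors and distractor edges, kept at
    least one ROI half-width away from any true spot.  Centers are unique;
    asking for more patches than the scenario supplies is an error.

    Patches are pooled from ``n_movies`` independent realizations of the
    scenario (seeds ``seed .. seed+n_movies-1``), the way a user would
    annotate regions of interest across several movies; this diversifies the
    rare-but-important cases (a particle passing a bright organelle) that a
    single short movie may miss.
    """
    if n_movies > 1:
        per_pos = -(-n_pos // n_movies)   # ceil split across movies
        per_neg = -(-n_neg // n_movies)
        parts = [
            render_training_patches(
                ScenarioParams(**{**params.__dict__, "seed": params.seed + k}),
                per_pos, per_neg, roi_px, n_movies=1,
            )
            for k in range(n_movies)
        ]
        patches = np.concatenate([p.patches for p in parts])
        labels = np.concatenate([p.labels for p in parts])
        keep_pos = np.where(labels == 1)[0][:n_pos]
        keep_neg = np.where(labels == 0)[0][:n_neg]
        keep = np.concatenate([keep_pos, keep_neg])
        return LabeledPatches(patches=patches[keep], labels=labels[keep],
                              roi_px=roi_px)
    if roi_px < 8 or roi_px % 2:
        raise ValueError("roi_px must be even and ≥ 8")
    seq, gt = simulate(params)
    rng = np.random.default_rng(params.seed + 1)
    half = roi_px // 2
    H, W = params.H, params.W

    def in_bounds(cx: int, cy: int) -> bool:
        return half <= cx <= W - half and half <= cy <= H - half

    # positive supply: every (frame, particle) position
    supply = [
        (d.frame, d.x, d.y) for tr in gt.tracks for d in tr
    ]
    rng.shuffle(supply)
    spots_by_frame: dict[int, list[tuple[float, float]]] = {}
    for f, x, y in supply:
        spots_by_frame.setdefault(f, []).append((x, y))

    patches: list[np.ndarray] = []
    labels: list[int] = []
    used: set[tuple[int, int, int]] = set()

    def cut(f: int, cx: int, cy: int) -> np.ndarray:
        return seq.frames[f, cy - half : cy + half, cx - half : cx + half].astype(float)

    for f, x, y in supply:
        if len(patches) >= n_pos:
            break
        cx = int(round(x)) + int(rng.integers(-1, 2))
        cy = int(round(y)) + int(rng.integers(-1, 2))
        if not in_bounds(cx, cy) or (f, cx, cy) in used:
            continue
        used.add((f, cx, cy))
        patches.append(cut(f, cx, cy))
        labels.append(1)
    if len(patches) < n_pos:
        raise ValueError(
            f"scenario supplies only {len(patches)} distinct positive patches"
        )

    def far_from_spots(f: int, cx: int, cy: int) -> bool:
        return all(
            (cx - sx) ** 2 + (cy - sy) ** 2 > half**2
            for sx, sy in spots_by_frame.get(f, [])
        )

    neg_centers: list[tuple[int, int, int]] = []
    n_distract = len(gt.distractors)
    attempts = 0
    while len(neg_centers) < n_neg and attempts < 200 * n_neg:
        attempts += 1
        f = int(rng.integers(0, params.T))
        kind = int(rng.integers(0, 3)) if n_distract else 0
        if kind == 0:
            # plain background, snapped to the local noise maximum: the
            # detector only ever asks about local maxima, so easy off-peak
            # background patches would understate the negative class
            cx = int(rng.integers(half, W - half + 1))
            cy = int(rng.integers(half, H - half + 1))
            r = 3
            y_lo, x_lo = max(0, cy - r), max(0, cx - r)
            win = seq.frames[f, y_lo : cy + r + 1, x_lo : cx + r + 1]
            dy, dx = np.unravel_index(int(np.argmax(win)), win.shape)
            cy, cx = y_lo + int(dy), x_lo + int(dx)
        else:
            j = int(rng.integers(0, n_distract))
            dx, dy, dsig, _ = gt.distractors[j]
            radius = 0.0 if kind == 1 else 2.0 * dsig  # interior vs edge
            ang = rng.uniform(0, 2 * math.pi)
            cx = int(round(dx + radius * math.cos(ang))) + int(rng.integers(-1, 2))
            cy = int(round(dy + radius * math.sin(ang))) + int(rng.integers(-1, 2))
        if not in_bounds(cx, cy) or (f, cx, cy) in used:
            continue
        if not far_from_spots(f, cx, cy):
            continue
        used.add((f, cx, cy))
        neg_centers.append((f, cx, cy))
    if len(neg_centers) < n_neg:
        raise ValueError(
            f"scenario supplies only {len(neg_centers)} distinct negative patches"
        )
    for f, cx, cy in neg_centers:
        patches.append(cut(f, cx, cy))
        labels.append(0)

    return LabeledPatches(
        patches=np.stack(patches), labels=np.array(labels, dtype=int), roi_px=roi_px
    )
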