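"""Frame enhancement before detection.

Three steps, each optional and independently testable:

* sliding-window background subtraction — the background at frame ``i`` is
  the per-pixel mean (or median) over the ``m``-frame window centered on
  ``i``, truncated at the sequence ends; the result is clipped at zero;
* contrast-limited adaptive histogram equalization (CLAHE), applied per
  frame after min–max normalization so the mapping is invariant to global
  affine intensity changes;
* translational registration maximizing the mutual information between each
  frame and its (already registered) predecessor, with a coarse integer grid
  search refined by a parabolic fit.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import ndimage
from skimage import exposure

from spotlink.config import PreprocessParams
from spotlink.core import ImageSequence

__all__ = [
    "subtract_background",
    "equalize",
    "register",
    "preprocess_sequence",
]

log = logging.getLogger(__name__)


def subtract_background(
    seq: ImageSequence, m: int, stat: str = "mean"
) -> ImageSequence:
    """Subtract a per-pixel temporal background estimated over ``m`` frames.

    The window is centered on the current frame and truncated at the ends.
    Output is floating-valued and clipped at zero.
    """
    T = seq.n_frames
    if not 1 <= m <= T:
        raise ValueError(f"m must be in [1, {T}], got {m}")
    frames = seq.frames.astype(float)
    out = np.empty_like(frames)
    half = (m - 1) // 2
    for i in range(T):
        lo = max(0, i - half)
        hi = min(T, lo + m)
        lo = max(0, hi - m)
        window = frames[lo:hi]
        bg = np.mean(window, axis=0) if stat == "mean" else np.median(window, axis=0)
        out[i] = np.maximum(frames[i] - bg, 0.0)
    return replace(seq, frames=out)


def equalize(frame: np.ndarray, clip: float = 0.01, tile_px: int = 32) -> np.ndarray:
    """CLAHE on one non-negative frame; output in [0, 1].

    The frame is min–max normalized first, so two frames identical up to a
    global affine intensity map produce identical outputs.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.min() < 0:
        raise ValueError("frame must be non-negative")
    H, W = frame.shape
    if tile_px > min(H, W):
        raise ValueError(f"tile_px {tile_px} larger than frame {frame.shape}")
    lo, hi = frame.min(), frame.max()
    if hi == lo:
        return np.zeros_like(frame)
    norm = (frame - lo) / (hi - lo)
    return exposure.equalize_adapthist(
        norm, kernel_size=tile_px, clip_limit=clip
    )


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """MI of the joint 32-bin intensity histogram of two equal-shape images."""
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _parabolic_peak(values: np.ndarray, idx: int) -> float:
    """Subsample offset of a peak from its two neighbors (−0.5..0.5)."""
    if idx == 0 or idx == len(values) - 1:
        return 0.0
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return 0.0
    return float(0.5 * (y0 - y2) / denom)


def _estimate_shift(
    ref: np.ndarray, mov: np.ndarray, max_shift: int = 5
) -> tuple[float, float]:
    """Translation (dx, dy) maximizing MI of ``mov`` shifted onto ``ref``."""
    offsets = np.arange(-max_shift, max_shift + 1)
    mi = np.full((len(offsets), len(offsets)), -np.inf)
    for iy, dy in enumerate(offsets):
        for ix, dx in enumerate(offsets):
            shifted = np.roll(np.roll(mov, dy, axis=0), dx, axis=1)
            crop = max_shift
            mi[iy, ix] = _mutual_information(
                ref[crop:-crop, crop:-crop], shifted[crop:-crop, crop:-crop]
            )
    iy, ix = np.unravel_index(np.argmax(mi), mi.shape)
    dy = offsets[iy] + _parabolic_peak(mi[:, ix], iy)
    dx = offsets[ix] + _parabolic_peak(mi[iy, :], ix)
    return float(dx), float(dy)


def register(
    seq: ImageSequence, max_shift: int = 5
) -> tuple[ImageSequence, list[tuple[float, float]]]:
    """Register a sequence by per-frame translation against the previous
    registered frame; returns the corrected sequence and the applied shifts.

    Shifts are cumulative: frame ``i`` is moved by the sum of all estimated
    inter-frame translations up to ``i``, applied by spline interpolation.
    """
    if seq.n_frames < 2:
        raise ValueError("registration needs at least two frames")
    frames = seq.frames.astype(float)
    out = np.empty_like(frames)
    out[0] = frames[0]
    shifts: list[tuple[float, float]] = [(0.0, 0.0)]
    cum = np.zeros(2)
    for i in range(1, seq.n_frames):
        try:
            dx, dy = _estimate_shift(out[i - 1], frames[i], max_shift)
        except Exception:  # pragma: no cover - optimizer failure fallback
            log.warning("registration failed at frame %d; identity shift used", i)
            dx, dy = 0.0, 0.0
        cum += (dx, dy)
        # ndimage.shift moves content by +offset along (row, col)
        out[i] = ndimage.shift(frames[i], (cum[1], cum[0]), order=1, mode="nearest")
        shifts.append((float(cum[0]), float(cum[1])))
    return replace(seq, frames=out), shifts


def preprocess_sequence(
    seq: ImageSequence, params: PreprocessParams
) -> ImageSequence:
    """Full enhancement chain: (register) → background subtract → CLAHE."""
    out = seq
    if params.register:
        out, _ = register(out)
    out = subtract_background(out, params.m, params.background_stat)
    eq = np.stack(
        [equalize(f, params.clahe_clip, params.clahe_tile_px) for f in out.frames]
    )
    return replace(out, frames=eq)
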