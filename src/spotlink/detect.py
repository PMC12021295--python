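"""Per-frame particle detection.

The multiscale spot-enhancing filter (MSSEF) applies a ladder of
Laplacian-of-Gaussian filters sequentially.  Iteration ``k`` computes

    f_k = LoG(σ_k) ∗ (b_{k-1} · g),        b_0 ≡ 1,

where ``g`` is the (preprocessed) frame and ``b_{k-1}`` the binary mask from
the previous iteration; after each iteration the mask is updated to
``f_k > T_k`` with the intensity threshold

    T_k = μ_k + c · ς_k,

μ_k/ς_k being the mean and standard deviation of the iteration's response
image and ``c`` a user weight.  The LoG is scale-normalized (×σ²) and negated
so bright spots give positive peaks comparable across the σ ladder.

Candidates are the local maxima of the final response inside the final mask;
each candidate's ROI is scored by the trained patch classifier, and accepted
candidates are localized to subpixel precision by iterative center-of-mass
refinement.  Classification, refinement and the ROI brightness statistic all
use the *raw* frame (the same kind of image the classifier was trained on);
preprocessing only sharpens candidate finding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from spotlink.cnn import ClassifierModel, classify
from spotlink.config import DetectParams, PreprocessParams
from spotlink.core import Detection, ImageSequence
from spotlink.preprocess import preprocess_sequence

__all__ = [
    "CandidateSpot",
    "MSSEFResult",
    "mssef",
    "find_candidates",
    "extract_roi",
    "refine_subpixel",
    "detect_frame",
    "detect_sequence",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateSpot:
    frame: int
    x: int
    y: int
    response: float


@dataclass
class MSSEFResult:
    """Final filter response and mask plus the per-iteration thresholds."""

    f: np.ndarray
    b: np.ndarray
    thresholds: list[float] = field(default_factory=list)
    means: list[float] = field(default_factory=list)
    sds: list[float] = field(default_factory=list)


def mssef(frame: np.ndarray, params: DetectParams) -> MSSEFResult:
    """Run the multiscale spot-enhancing filter on one frame."""
    if not params.sigmas:
        raise ValueError("sigmas must be non-empty")
    sig = list(params.sigmas)
    if any(s <= 0 for s in sig) or any(b <= a for a, b in zip(sig, sig[1:])):
        raise ValueError("sigmas must be strictly increasing and positive")
    g = np.asarray(frame, dtype=float)
    b = np.ones_like(g)
    result = MSSEFResult(f=np.zeros_like(g), b=b)
    for sigma in sig:
        # scale-normalized LoG, negated: bright blobs → positive response
        f = -(sigma**2) * ndimage.gaussian_laplace(b * g, sigma)
        mu = float(f.mean())
        sd = float(f.std())
        t = mu + params.c * sd
        # degenerate flat response (e.g. constant frame): nothing to enhance
        b = (f > t).astype(float) if sd > 1e-9 else np.zeros_like(f)
        result.f = f
        result.b = b
        result.thresholds.append(t)
        result.means.append(mu)
        result.sds.append(sd)
    return result


def find_candidates(
    result: MSSEFResult, min_peak_sep_px: float, frame_index: int = 0
) -> list[CandidateSpot]:
    """Local maxima (3×3 neighborhood) of the response within the mask;
    peaks closer than ``min_peak_sep_px`` merge keeping the higher response."""
    f, b = result.f, result.b
    if not b.any():
        return []
    local_max = f == ndimage.maximum_filter(f, size=3, mode="nearest")
    ys, xs = np.nonzero(local_max & (b > 0))
    order = np.argsort(f[ys, xs])[::-1]
    kept: list[CandidateSpot] = []
    sep2 = min_peak_sep_px**2
    for i in order:
        x, y = int(xs[i]), int(ys[i])
        if any((x - k.x) ** 2 + (y - k.y) ** 2 < sep2 for k in kept):
            continue
        kept.append(CandidateSpot(frame=frame_index, x=x, y=y,
                                  response=float(f[y, x])))
    kept.sort(key=lambda c: (c.y, c.x))
    return kept


def extract_roi(
    frame: np.ndarray, candidate: CandidateSpot, roi_px: int
) -> np.ndarray | None:
    """Patch of ``roi_px``² centered on the candidate (center at pixel
    (roi_px/2, roi_px/2)); candidates too close to a border are rejected."""
    if roi_px % 2:
        raise ValueError("roi_px must be even")
    half = roi_px // 2
    H, W = frame.shape
    x, y = candidate.x, candidate.y
    if x < half or y < half or x > W - half or y > H - half:
        return None
    return np.asarray(frame[y - half : y + half, x - half : x + half], dtype=float)


def refine_subpixel(
    frame: np.ndarray,
    candidate: CandidateSpot,
    refine_radius_px: int = 4,
    refine_iters: int = 20,
    p_spot: float = 1.0,
    roi_mean: float | None = None,
) -> Detection:
    """Iterative center-of-mass refinement to subpixel precision.

    Each iteration takes the window of radius ``refine_radius_px`` around the
    current estimate, subtracts the window minimum, and moves the estimate to
    the intensity centroid; it stops when the step falls below 0.01 px.  An
    all-zero (uniform) window leaves the position unchanged.
    """
    frame = np.asarray(frame, dtype=float)
    H, W = frame.shape
    r = refine_radius_px
    x, y = float(candidate.x), float(candidate.y)
    for _ in range(refine_iters):
        cx, cy = int(round(x)), int(round(y))
        x_lo, x_hi = max(0, cx - r), min(W, cx + r + 1)
        y_lo, y_hi = max(0, cy - r), min(H, cy + r + 1)
        window = frame[y_lo:y_hi, x_lo:x_hi] - frame[y_lo:y_hi, x_lo:x_hi].min()
        total = window.sum()
        if total <= 0:
            break
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        nx = float((window * xx).sum() / total)
        ny = float((window * yy).sum() / total)
        step = np.hypot(nx - x, ny - y)
        x, y = nx, ny
        if step < 0.01:
            break
    if roi_mean is None:
        roi_mean = float(frame[max(0, int(y) - r):int(y) + r + 1,
                                max(0, int(x) - r):int(x) + r + 1].mean())
    return Detection(frame=candidate.frame, x=x, y=y, p_spot=p_spot,
                     roi_mean=roi_mean)


def detect_frame(
    raw_frame: np.ndarray,
    enhanced_frame: np.ndarray,
    model: ClassifierModel | None,
    params: DetectParams,
    frame_index: int = 0,
) -> tuple[list[Detection], int]:
    """Detect particles in one frame.

    Returns the accepted detections and the pre-classifier candidate count.
    With ``model=None`` classification is skipped (every in-bounds candidate
    is accepted with ``p_spot=1``).
    """
    result = mssef(enhanced_frame, params)
    candidates = find_candidates(result, params.min_peak_sep_px, frame_index)
    rois, kept = [], []
    for cand in candidates:
        roi = extract_roi(raw_frame, cand, params.roi_px)
        if roi is not None:
            rois.append(roi)
            kept.append(cand)
    if not kept:
        return [], len(candidates)
    if model is not None:
        probs = classify(model, np.stack(rois))
    else:
        probs = np.ones(len(kept))
    detections = []
    for cand, roi, p in zip(kept, rois, probs):
        if p < params.p_min:
            continue
        detections.append(
            refine_subpixel(
                raw_frame,
                cand,
                params.refine_radius_px,
                params.refine_iters,
                p_spot=float(p),
                roi_mean=float(roi.mean()),
            )
        )
    return detections, len(candidates)


def detect_sequence(
    seq: ImageSequence,
    model: ClassifierModel | None,
    params: DetectParams,
    preprocess_params: PreprocessParams | None = None,
) -> list[list[Detection]]:
    """Detect particles in every frame of a sequence.

    The sequence is enhanced (background subtraction + CLAHE) for candidate
    finding; classification and localization use the raw frames.
    """
    pp = preprocess_params or PreprocessParams()
    enhanced = preprocess_sequence(seq, pp)
    per_frame: list[list[Detection]] = []
    for t in range(seq.n_frames):
        dets, n_cand = detect_frame(
            seq.frames[t].astype(float), enhanced.frames[t], model, params, t
        )
        log.debug("frame %d: %d candidates, %d accepted", t, n_cand, len(dets))
        per_frame.append(dets)
    return per_frame
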