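"""Core containers and coordinate conventions.

Conventions used throughout the package:

* ``x`` is the column index, ``y`` the row index, both 0-based, with pixel
  centers at integer coordinates.
* Tracks are stored in pixel/frame units; physical quantities (µm, s) are
  derived on demand from ``pixel_size_nm`` and ``frame_interval_s`` metadata.
  Analytics that need physical units fail loudly when metadata is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Detection",
    "ImageSequence",
    "Track",
    "TrackSet",
    "MissingMetadataError",
]


class MissingMetadataError(ValueError):
    """Raised when a physical-unit computation lacks pixel size or frame interval."""


@dataclass
class ImageSequence:
    """An ordered stack of grayscale frames with optional physical metadata.

    Parameters
    ----------
    frames:
        ``(T, H, W)`` non-negative intensity array.
    pixel_size_nm:
        Physical edge length of one pixel in nanometres, or ``None``.
    frame_interval_s:
        Time between consecutive frames in seconds, or ``None``.
    bit_depth:
        Declared bit depth, 8 or 16.
    """

    frames: np.ndarray
    pixel_size_nm: float | None = None
    frame_interval_s: float | None = None
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T×H×W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("sequence must contain at least one frame")
        if np.issubdtype(self.frames.dtype, np.integer) and self.frames.size:
            if self.frames.min() < 0:
                raise ValueError("negative intensities")
            if self.frames.max() >= 2**self.bit_depth:
                raise ValueError(
                    f"intensities exceed declared bit depth {self.bit_depth}"
                )
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.frames.shape)  # type: ignore[return-value]

    def require_metadata(self) -> tuple[float, float]:
        """Return ``(pixel_size_nm, frame_interval_s)`` or raise."""
        if self.pixel_size_nm is None or self.frame_interval_s is None:
            raise MissingMetadataError(
                "pixel_size_nm and frame_interval_s are required for physical units"
            )
        return float(self.pixel_size_nm), float(self.frame_interval_s)


@dataclass(frozen=True)
class Detection:
    """One particle observation in one frame.

    ``x``/``y`` are subpixel pixel coordinates; ``p_spot`` the classifier
    probability that the patch contains a particle; ``roi_mean`` the mean
    intensity of the patch used for appearance evidence and brightness stats.
    """

    frame: int
    x: float
    y: float
    p_spot: float = 1.0
    roi_mean: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_spot <= 1.0:
            raise ValueError("p_spot must lie in [0, 1]")


@dataclass
class Track:
    """An ordered run of detections; frame gaps are allowed.

    ``join_passes`` records, for multi-pass linking, at which pass each
    tracklet join occurred (empty for tracks never joined).
    """

    id: int
    detections: list[Detection] = field(default_factory=list)
    join_passes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError(f"track {self.id}: frame indices must strictly increase")

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self) -> Iterator[Detection]:
        return iter(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def xy(self) -> np.ndarray:
        """``(N, 2)`` array of (x, y) positions in pixels."""
        return np.array([[d.x, d.y] for d in self.detections], dtype=float)

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame

    def net_length_px(self) -> float:
        p = self.xy
        if len(p) < 2:
            return 0.0
        return float(np.hypot(*(p[-1] - p[0])))


@dataclass
class TrackSet:
    """A collection of tracks plus the movie metadata they were extracted from."""

    tracks: list[Track] = field(default_factory=list)
    source: str = ""
    pixel_size_nm: float | None = None
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        ids = [t.id for t in self.tracks]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate track ids: {dup}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def require_metadata(self) -> tuple[float, float]:
        if self.pixel_size_nm is None or self.frame_interval_s is None:
            raise MissingMetadataError(
                "pixel_size_nm and frame_interval_s are required for physical units"
            )
        return float(self.pixel_size_nm), float(self.frame_interval_s)

    def with_tracks(self, tracks: Sequence[Track]) -> "TrackSet":
        return replace(self, tracks=list(tracks))
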