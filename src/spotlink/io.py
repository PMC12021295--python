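"""Reading and writing movies, track sets and per-track measure tables.

Movies are multi-page grayscale TIFF (8/16-bit).  Tracks are stored as JSON
with one record per track: ``{id, frames[], x[], y[], brightness[]}`` plus
file-level metadata; coordinates stay in pixel/frame units so files remain
valid without physical metadata.  All writers are deterministic: identical
inputs produce byte-identical files (no timestamps inside data files).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import tifffile

from spotlink.core import Detection, ImageSequence, Track, TrackSet

if TYPE_CHECKING:  # pragma: no cover
    from spotlink.trajectory import TrajectoryMeasures

__all__ = [
    "read_sequence",
    "write_sequence",
    "read_tracks",
    "write_tracks",
    "export_measures_csv",
    "read_measures_csv",
]

_FMT = ".9g"  # ≥6 significant digits on persisted coordinates


def read_sequence(
    path: str | Path,
    pixel_size_nm: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageSequence:
    """Read a multi-page grayscale TIFF as an image sequence.

    Metadata is taken from explicit arguments and is otherwise absent.
    RGB or multi-channel pages are rejected as an unsupported layout.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"unsupported layout: expected grayscale pages, got shape {arr.shape}"
        )
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError("unsupported layout: RGB/multi-channel TIFF")
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return ImageSequence(
        frames=arr,
        pixel_size_nm=pixel_size_nm,
        frame_interval_s=frame_interval_s,
        bit_depth=bit_depth,
    )


def write_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write a sequence as a multi-page TIFF in its declared bit depth."""
    dtype = np.uint8 if seq.bit_depth == 8 else np.uint16
    frames = np.clip(np.rint(seq.frames), 0, 2**seq.bit_depth - 1).astype(dtype)
    tifffile.imwrite(str(path), frames, photometric="minisblack")


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    """Serialize a track set to JSON (pixel/frame units)."""
    payload = {
        "source": tracks.source,
        "pixel_size_nm": tracks.pixel_size_nm,
        "frame_interval_s": tracks.frame_interval_s,
        "tracks": [
            {
                "id": t.id,
                "frames": [int(d.frame) for d in t],
                "x": [float(format(d.x, _FMT)) for d in t],
                "y": [float(format(d.y, _FMT)) for d in t],
                "brightness": [float(format(d.roi_mean, _FMT)) for d in t],
                "p_spot": [float(format(d.p_spot, _FMT)) for d in t],
                "join_passes": list(t.join_passes),
            }
            for t in tracks
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_tracks(path: str | Path) -> TrackSet:
    """Read a JSON track file; duplicate ids or malformed records are errors."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed track file {path}: {e}") from e
    if not isinstance(payload, dict) or "tracks" not in payload:
        raise ValueError(f"malformed track file {path}: missing 'tracks'")
    tracks = []
    for rec in payload["tracks"]:
        n = len(rec["frames"])
        if not (len(rec["x"]) == len(rec["y"]) == n):
            raise ValueError(f"malformed track {rec.get('id')}: ragged arrays")
        brightness = rec.get("brightness") or [0.0] * n
        p_spot = rec.get("p_spot") or [1.0] * n
        dets = [
            Detection(
                frame=int(rec["frames"][i]),
                x=float(rec["x"][i]),
                y=float(rec["y"][i]),
                p_spot=float(p_spot[i]),
                roi_mean=float(brightness[i]),
            )
            for i in range(n)
        ]
        tracks.append(
            Track(id=int(rec["id"]), detections=dets,
                  join_passes=list(rec.get("join_passes", [])))
        )
    return TrackSet(
        tracks=tracks,
        source=payload.get("source", ""),
        pixel_size_nm=payload.get("pixel_size_nm"),
        frame_interval_s=payload.get("frame_interval_s"),
    )


_MEASURE_COLUMNS = [
    "track_id", "first_frame", "last_frame", "n_points",
    "d_total_um", "d_net_um", "d_max_um", "t_traj_s", "theta_net_deg",
    "b_mean", "v_curvilinear_um_s", "v_line_um_s", "v_max_segment_um_s",
    "n_moving_segments", "t_avg_moving_s",
]


def export_measures_csv(
    measures: Sequence["TrajectoryMeasures"], path: str | Path
) -> None:
    """Write one CSV row per track with every trajectory measure.

    An empty list writes the header only.
    """
    rows = [
        {
            "track_id": m.track_id,
            "first_frame": m.first_frame,
            "last_frame": m.last_frame,
            "n_points": m.n_points,
            "d_total_um": m.d_total_um,
            "d_net_um": m.d_net_um,
            "d_max_um": m.d_max_um,
            "t_traj_s": m.t_traj_s,
            "theta_net_deg": m.theta_net_deg,
            "b_mean": m.b_mean,
            "v_curvilinear_um_s": m.v_curvilinear_um_s,
            "v_line_um_s": m.v_line_um_s,
            "v_max_segment_um_s": m.v_max_segment_um_s,
            "n_moving_segments": m.n_moving_segments,
            "t_avg_moving_s": m.t_avg_moving_s,
        }
        for m in measures
    ]
    df = pd.DataFrame(rows, columns=_MEASURE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_measures_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def export_polar_csv(hist, path: str | Path) -> None:
    """Write a polar heading histogram as CSV (one row per 10° bin)."""
    df = pd.DataFrame(
        {
            "bin_start_deg": hist.bin_edges_deg[:-1],
            "bin_end_deg": hist.bin_edges_deg[1:],
            "count": hist.counts.astype(int),
            "count_per_min": hist.counts_per_min,
            "net_distance_sum_um": hist.net_distance_um,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")
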