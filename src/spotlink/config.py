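"""Configuration: every tunable parameter of the pipeline, with YAML round-trip.

One config file describes one reproducible run.  Defaults are documented on
each dataclass field; the file representation is a nested YAML mapping that
round-trips losslessly (`Config.load(path)` after `cfg.save(path)` compares
equal).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "Config",
    "PreprocessParams",
    "DetectParams",
    "LinkParams",
    "TrajectoryParams",
    "EvaluateParams",
    "ScenarioParams",
    "default_cpts",
]


def default_cpts() -> dict[str, Any]:
    """Default conditional probability tables for the connectivity network.

    Each evidence node has three ordinal states (0 = most favorable for a
    join); the tables give P(state | CS) for CS in {True, False}.  States that
    favor connectivity multiply the posterior odds of CS=True.  The ``seq``
    node states are derived from the order/overlap parents:
    0 = in order without temporal overlap, 1 = temporal overlap, 2 = reversed.
    """
    return {
        "prior_true": 0.5,
        "intensity": {"true": [0.60, 0.30, 0.10], "false": [0.33, 0.33, 0.34]},
        "orientation": {"true": [0.65, 0.25, 0.10], "false": [0.25, 0.35, 0.40]},
        "speed": {"true": [0.60, 0.30, 0.10], "false": [0.33, 0.33, 0.34]},
        "distance": {"true": [0.60, 0.30, 0.10], "false": [0.20, 0.30, 0.50]},
        "gap": {"true": [0.70, 0.20, 0.10], "false": [0.40, 0.30, 0.30]},
        "seq": {"true": [0.90, 0.09, 0.01], "false": [0.50, 0.30, 0.20]},
    }


def _default_thresholds() -> dict[str, list[float]]:
    """Discretization cut points for the evidence variables (3 states each).

    intensity/speed: ratios (max/min ≥ 1); orientation: absolute heading
    difference in degrees; distance: end-to-start distance as a fraction of
    the pair gate; gap: frame gap.
    """
    return {
        "intensity_ratio": [1.3, 2.0],
        "angle_deg": [45.0, 120.0],
        "speed_ratio": [1.5, 3.0],
        "speed_floor_px": 1.0,
        "distance_frac": [1.0 / 3.0, 2.0 / 3.0],
        "gap_frames": [1.0, 3.0],
    }


@dataclass
class PreprocessParams:
    m: int = 20                 # frames in the centered background window
    background_stat: str = "mean"   # "mean" or "median" over the window
    clahe_clip: float = 0.01    # CLAHE clip limit
    clahe_tile_px: int = 32     # CLAHE tile edge, px
    register: bool = False      # translational registration on/off


@dataclass
class DetectParams:
    sigmas: list[float] = field(default_factory=lambda: [1.0, 1.5, 2.5, 4.0])
    c: float = 0.8              # threshold weight: T = mean + c*sd
    roi_px: int = 16            # classifier patch edge (even)
    p_min: float = 0.5          # classifier acceptance probability
    min_peak_sep_px: float = 3.0
    refine_iters: int = 20
    refine_radius_px: int = 4   # center-of-mass window radius


@dataclass
class ClassifierParams:
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class LinkParams:
    max_link_dist_px: float = 5.0
    max_missed_frames: int = 2
    max_tracklet_len: int = 10
    pair_gate_px: float = 15.0
    pair_gate_frames: int = 5
    score_min: float = 0.5
    overlap_tolerance_frames: int = 2   # max temporal overlap still scored
    passes: list[dict] = field(default_factory=lambda: [{}])
    cpts: dict = field(default_factory=default_cpts)
    thresholds: dict = field(default_factory=_default_thresholds)


@dataclass
class TrajectoryParams:
    msd_window: int = 5         # points per rolling MSD window
    msd_lags: int = 3           # lags used for the log-log slope
    msd_alpha_moving: float = 1.4   # exponent threshold for "moving"
    speed_window_s: float = 1.0     # sliding window for max curvilinear speed
    min_points: int = 3
    min_net_len_nm: float = 700.0


@dataclass
class EvaluateParams:
    epsilon_px: float = 5.0     # point-match gate
    gamma_min_cover: float = 0.5    # matched fraction for a gt track to count detected
    candidate_radius_px: float = 50.0   # centroid pre-filter for track pairs


@dataclass
class ScenarioParams:
    """Synthetic movie scenario; defaults are the standard evaluation conditions."""

    T: int = 100
    H: int = 512
    W: int = 512
    n_particles: int | None = None  # explicit count; else from density preset
    density: str = "low"        # low/middle/high = 10/50/100 per 512×512 frame
    snr: float = 7.0            # Poisson SNR at the spot peak
    psf_sigma_px: float = 1.3   # spot Gaussian sd
    motion: str = "switching"   # directed | brownian | switching
    speed_px: float = 2.0       # directed speed, px/frame
    heading_deg: float | None = None    # fixed heading; None = random per particle
    diffusion_sd_px: float = 0.5        # Brownian step sd
    dwell_moving: float = 10.0  # mean moving dwell, frames (switching)
    dwell_paused: float = 5.0   # mean paused dwell, frames (switching)
    n_distractors: int = 10     # immobile Golgi-like blobs
    background_level: float = 30.0  # mean background counts
    pixel_size_nm: float = 100.0
    frame_interval_s: float = 0.22  # ~4.5 fps
    margin_px: float = 16.0     # particles reflect off this interior margin
    seed: int = 0


_GROUPS = {
    "preprocess": PreprocessParams,
    "detect": DetectParams,
    "classifier": ClassifierParams,
    "link": LinkParams,
    "trajectory": TrajectoryParams,
    "evaluate": EvaluateParams,
    "synthetic": ScenarioParams,
}


@dataclass
class Config:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detect: DetectParams = field(default_factory=DetectParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    link: LinkParams = field(default_factory=LinkParams)
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)
    evaluate: EvaluateParams = field(default_factory=EvaluateParams)
    synthetic: ScenarioParams = field(default_factory=ScenarioParams)

    def to_dict(self) -> dict[str, Any]:
        return {name: dataclasses.asdict(getattr(self, name)) for name in _GROUPS}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Config":
        kwargs = {}
        for name, group_cls in _GROUPS.items():
            sub = dict(d.get(name, {}))
            known = {f.name for f in dataclasses.fields(group_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown {name} parameters: {sorted(unknown)}")
            kwargs[name] = group_cls(**sub)
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def load(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"malformed config file: {path}")
        return cls.from_dict(data)
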