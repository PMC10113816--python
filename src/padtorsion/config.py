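"""Pipeline configuration: every stage parameter with its reference default.

The defaults are the constants of the reference acquisition and analysis:
Gaussian displacement smoothing (window 16, sigma 0.75 frames), slip
threshold 0.6 deg/frame, stick-ratio cutoff 0.03, 85 px/mm, zero-phase
Butterworth order 2 at 5 Hz, T_slip over the 0.5 s before 75 degrees of
twist, and skin elasticity E = 1 MPa, nu = 0.4 over a 2 mm depth.
All of them can be overridden from a YAML config file or CLI flags; the
seed is mandatory wherever synthetic data is produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    smoothing_window: int = 16
    smoothing_sigma_frames: float = 0.75
    slip_threshold_deg_per_frame: float = 0.6
    stick_cutoff: float = 0.03
    px_per_mm: float = 85.0
    butter_order: int = 2
    butter_cutoff_hz: float = 5.0
    tslip_anchor_deg: float = 75.0
    tslip_window_s: float = 0.5
    young_modulus_pa: float = 1e6
    poisson_ratio: float = 0.4
    energy_depth_m: float = 2e-3
    boundary_grid_px: float = 4.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.smoothing_sigma_frames <= 0:
            raise ValueError("smoothing_sigma_frames must be positive")
        if self.slip_threshold_deg_per_frame <= 0:
            raise ValueError("slip threshold must be positive")
        if not (0 < self.stick_cutoff < 1):
            raise ValueError("stick_cutoff must lie in (0, 1)")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")
        if self.butter_cutoff_hz <= 0:
            raise ValueError("butter_cutoff_hz must be positive")
        if self.tslip_window_s <= 0:
            raise ValueError("tslip_window_s must be positive")
        if self.young_modulus_pa <= 0:
            raise ValueError("young_modulus_pa must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.energy_depth_m <= 0:
            raise ValueError("energy_depth_m must be positive")
        if self.boundary_grid_px <= 0:
            raise ValueError("boundary_grid_px must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path, require_seed: bool = False) -> dict:
    """Load a YAML config file into a plain dict (empty file -> {})."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    if require_seed and data.get("seed") is None:
        raise ValueError(
            f"config file {path} is missing the mandatory 'seed' entry; "
            "synthetic trials must be reproducible"
        )
    return data


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping (for run manifests)."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
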