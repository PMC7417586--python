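"""Validated run configuration for the command-line pipeline.

Configs are JSON or YAML files validated with pydantic before any
computation starts; every run writes the resolved configuration (with its
hash) next to its outputs for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "RunConfig", "CalibrateConfig", "SimulateConfig", "TrackConfig",
    "AnalyzeConfig", "PoresConfig", "StatsConfig", "load_config",
    "config_hash",
]


class CalibrateConfig(BaseModel):
    input_csv: str | None = None          # columns current_A, distance_um, velocity_um_s
    simulate: bool = False
    viscosity_pa_s: float = 4.85          # 5000 cSt PDMS at 0.97 g/cm^3
    bead_radius_um: float = 2.25
    currents_A: list[float] = Field(default_factory=lambda: [0.2, 0.35, 0.5, 0.65, 0.8, 1.0])
    distances_um: list[float] = Field(default_factory=lambda: [70, 80, 90, 100, 110, 120])
    saturation_current_A: float = 1.0
    # injected ground truth for --simulate runs (force grows with current)
    true_F0: float = 700.0
    true_c1: float = -4.0
    true_c2: float = 1.0
    true_c3: float = 1.0
    drift_velocity_um_s: float = 0.1
    noise_sd_position_um: float = 0.0

    @field_validator("viscosity_pa_s", "bead_radius_um")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v


class SimulateConfig(BaseModel):
    kind: str = "creep"                   # creep | drag | images | collagen
    J0: float = 1.0 / 277.0
    beta: float = 0.46
    amplitude_nN: float = 1.0
    on_s: float = 2.0
    off_s: float = 2.0
    n_cycles: int = 1
    bead_radius_um: float = 2.25
    frame_rate_hz: float = 40.0
    noise_sd_position_um: float = 0.0
    n_beads: int = 1


class TrackConfig(BaseModel):
    input_tiff: str
    expected_diameter_um: float = 4.5
    min_correlation: float = 0.5


class AnalyzeConfig(BaseModel):
    trajectories: list[str] = Field(default_factory=list)  # CSV paths (may carry group prefix "group:path")
    protocol_json: str | None = None
    protocol: dict | None = None
    bead_radius_um: float = 2.25
    fit_model: str = "power_law"
    n_comparisons: int = 1
    groups: dict[str, list[str]] | None = None


class PoresConfig(BaseModel):
    input_tiff: str
    voxel_size_zyx_um: tuple[float, float, float] | None = None
    rescale_xy: float = 1.0
    min_radius_um: float | None = None
    sigma_vox: float = 1.0


class StatsConfig(BaseModel):
    input_csv: str                        # columns group, stiffness_pa, fluidity
    n_comparisons: int | None = None


class RunConfig(BaseModel):
    seed: int = 0
    log_level: str = "INFO"
    calibrate: CalibrateConfig | None = None
    simulate: SimulateConfig | None = None
    track: TrackConfig | None = None
    analyze: AnalyzeConfig | None = None
    pores: PoresConfig | None = None
    stats: StatsConfig | None = None


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.model_validate(data)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
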