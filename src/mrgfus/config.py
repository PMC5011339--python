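"""Run configuration: validated sections with explicit defaults.

Configs load from JSON or TOML; unknown keys and unit violations are
rejected with descriptive errors, and a loaded config round-trips through
``dump_config``/``load_config`` unchanged.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .controller import DEFAULT_KD, DEFAULT_KI, DEFAULT_KP, DEFAULT_V_MAX


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PIDSection(_Section):
    """Controller gains and clamp; defaults are the hand-tuned phantom values."""

    setpoint_C: float
    kp: float = Field(DEFAULT_KP, ge=0)
    ki: float = Field(DEFAULT_KI, ge=0)
    kd: float = Field(DEFAULT_KD, ge=0)
    v_max: float = Field(DEFAULT_V_MAX, gt=0)


class DoseSection(_Section):
    r_above: float = Field(0.5, gt=0, lt=1)
    r_below: float = Field(0.25, gt=0, lt=1)
    t_break_C: float = 43.0
    baseline_body_C: float = 37.0
    threshold_min: float | None = Field(None, gt=0)


class ThermometrySection(_Section):
    alpha_ppm_per_C: float = Field(-0.01, lt=0)
    gamma_Hz_per_T: float = Field(42.576e6, gt=0)
    unwrap_enabled: bool = False
    magnitude_floor_frac: float = Field(0.10, ge=0, le=1)
    drift_correction: bool = False


class AcquisitionSection(_Section):
    te_s: float = Field(0.010, gt=0)
    b0_T: float = Field(4.7, gt=0)
    frame_period_s: float = Field(3.0, gt=0)
    dummy_frames: int = Field(2, ge=0)


class RoiRect(_Section):
    """Rectangular ROI: centre and size in mm in image coordinates."""

    center_mm: tuple[float, float]
    size_mm: tuple[float, float]

    @field_validator("size_mm")
    @classmethod
    def _positive(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("ROI size must be positive")
        return v


class RunConfig(_Section):
    seed: int = 0
    preset: str = "agar-phantom"
    duration_s: float = Field(600.0, gt=0)
    pid: PIDSection
    dose: DoseSection = DoseSection()
    thermometry: ThermometrySection = ThermometrySection()
    acquisition: AcquisitionSection = AcquisitionSection()
    focus_roi: RoiRect | None = None
    drift_roi: RoiRect | None = None
    output_dir: str = "."


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or TOML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".toml":
        raw = tomllib.loads(path.read_text())
    else:
        raw = json.loads(path.read_text())
    return RunConfig.model_validate(raw)


def dump_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write a config (defaults made explicit) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(cfg.model_dump(), indent=2))
    return path
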