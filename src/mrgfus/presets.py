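"""Named rig presets shipped as TOML config files.

A preset bundles everything a closed-loop virtual sonication needs: tissue
plant, transducer source, scanner model, focal and drift-reference ROIs, and
dose baseline.  The scanner's per-pixel phase noise is derived at load time
from the preset's ``focal_noise_std_C`` — the standard deviation the noise
should induce on the focal-ROI mean temperature — so the documented
thermometry precision holds whatever the ROI pixel count.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, replace
from importlib import resources

from .dosimetry import DoseParams
from .rig import ScannerModel, SourceModel, TissueParams, image_pixel_mm
from .thermometry import DRIFT_REFERENCE, FOCUS, ROI, ThermometryConfig, prf_phase_per_C

PRESET_NAMES = ("agar-phantom", "mouse-tumor")


@dataclass(frozen=True)
class RigPreset:
    """A fully resolved rig configuration."""

    name: str
    tissue: TissueParams
    source: SourceModel
    scanner: ScannerModel
    focus_roi: ROI
    drift_roi: ROI
    dose_params: DoseParams
    dummy_frames: int


def phase_sigma_for_focal_std(
    focal_std_C: float,
    n_roi_pixels: int,
    te_s: float,
    b0_T: float,
    cfg: ThermometryConfig | None = None,
) -> float:
    """Per-pixel phase noise (rad) giving a target focal-ROI mean temperature std.

    Independent per-pixel noise averages down by sqrt(n), so
    sigma_phase = focal_std * sqrt(n) * |dphi/dT|.
    """
    cfg = cfg or ThermometryConfig()
    scale = abs(prf_phase_per_C(te_s, b0_T, cfg))
    return focal_std_C * math.sqrt(n_roi_pixels) * scale


def load_preset(
    name: str,
    rng_seed: int = 0,
    noise: bool = True,
    thermo_cfg: ThermometryConfig | None = None,
) -> RigPreset:
    """Load a shipped preset by name ("agar-phantom" or "mouse-tumor")."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    text = resources.files("mrgfus.data").joinpath(f"{name}.toml").read_text()
    raw = tomllib.loads(text)
    tissue = TissueParams(
        conductivity_W_mK=raw["tissue"]["conductivity_W_mK"],
        vol_heat_capacity_J_m3K=raw["tissue"]["vol_heat_capacity_J_m3K"],
        perfusion_per_s=raw["tissue"]["perfusion_per_s"],
        arterial_dT_C=raw["tissue"]["arterial_dT_C"],
        domain_mm=tuple(raw["tissue"]["domain_mm"]),
        grid_mm=raw["tissue"]["grid_mm"],
    )
    source = SourceModel(
        focus_center_mm=tuple(raw["source"]["focus_center_mm"]),
        fwhm_mm=tuple(raw["source"]["fwhm_mm"]),
        power_gain_W_per_V2=raw["source"]["power_gain_W_per_V2"],
        duty=raw["source"]["duty"],
    )
    shape = (tissue.shape[0], tissue.shape[2])
    pixel = image_pixel_mm(tissue)
    rois = raw["rois"]
    focus_roi = ROI.from_rect(
        tuple(rois["focus_center_mm"]), tuple(rois["focus_size_mm"]), pixel, shape, FOCUS
    )
    drift_roi = ROI.from_rect(
        tuple(rois["drift_center_mm"]),
        tuple(rois["drift_size_mm"]),
        pixel,
        shape,
        DRIFT_REFERENCE,
    )
    sc = raw["scanner"]
    sigma = 0.0
    if noise and sc["focal_noise_std_C"] > 0:
        sigma = phase_sigma_for_focal_std(
            sc["focal_noise_std_C"],
            focus_roi.n_pixels,
            sc["te_s"],
            sc["b0_T"],
            thermo_cfg,
        )
    scanner = ScannerModel(
        noise_sigma_phase_rad=sigma,
        drift_rate_rad_per_s=sc["drift_rate_rad_per_s"],
        slice_center_mm=sc["slice_center_mm"],
        slice_thickness_mm=sc["slice_thickness_mm"],
        frame_period_s=sc["frame_period_s"],
        rng_seed=rng_seed,
        te_s=sc["te_s"],
        b0_T=sc["b0_T"],
    )
    dose_params = DoseParams(baseline_body_C=raw["dose"]["baseline_body_C"])
    return RigPreset(
        name=name,
        tissue=tissue,
        source=source,
        scanner=scanner,
        focus_roi=focus_roi,
        drift_roi=drift_roi,
        dose_params=dose_params,
        dummy_frames=raw["loop"]["dummy_frames"],
    )


def with_seed(preset: RigPreset, rng_seed: int) -> RigPreset:
    """Copy of a preset with a different scanner seed."""
    return replace(preset, scanner=replace(preset.scanner, rng_seed=rng_seed))
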