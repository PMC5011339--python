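"""Virtual rig: bioheat tissue plant, virtual transducer, synthetic scanner.

A hardware stand-in that closes the control loop for tests and demos.  The
plant is a Pennes bioheat model on a 3-D grid,

    rho*c dT/dt = k lap(T) - rho*c * w * (T - T_a) + Q(x),

stepped with an explicit finite-difference scheme under zero-flux (insulated)
boundaries; w is a lumped loss rate (blood perfusion in tissue, coupling to
the water bath for a phantom).  The virtual transducer deposits a 3-D
Gaussian power density with the transducer's ellipsoidal focal FWHM and total
power gain * v^2 * duty (acoustic intensity scales with pressure squared and
pressure with drive voltage).  The synthetic scanner slice-averages the
temperature field, maps degC to phase through the inverse PRF relation, and
adds uniform field drift plus per-pixel complex Gaussian noise, reproducibly
seeded per frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Callable

import numpy as np

from .controller import PIDParams, SonicationLog, run_treatment
from .dosimetry import DoseParams
from .thermometry import (
    FOCUS,
    ROI,
    ComplexFrame,
    ThermometryConfig,
    prf_phase_per_C,
)


@dataclass(frozen=True)
class TissueParams:
    """Thermal properties and grid geometry of the simulated medium.

    ``perfusion_per_s`` is the lumped Pennes sink w*c_b/(rho*c): for live
    tissue it is blood perfusion, for a phantom an effective loss to the
    surrounding bath.  Defaults mimic an agar/soft-tissue phantom.
    """

    conductivity_W_mK: float = 0.6
    vol_heat_capacity_J_m3K: float = 4.2e6
    perfusion_per_s: float = 0.0
    arterial_dT_C: float = 0.0
    domain_mm: tuple[float, float, float] = (12.0, 12.0, 12.0)
    grid_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.conductivity_W_mK <= 0 or self.vol_heat_capacity_J_m3K <= 0:
            raise ValueError("conductivity and heat capacity must be positive")
        if self.perfusion_per_s < 0:
            raise ValueError("perfusion must be non-negative")
        if self.grid_mm <= 0 or any(d <= 0 for d in self.domain_mm):
            raise ValueError("grid and domain extents must be positive")
        object.__setattr__(self, "domain_mm", tuple(float(d) for d in self.domain_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        """Cell counts of the cell-centred finite-volume grid."""
        return tuple(max(1, int(round(d / self.grid_mm))) for d in self.domain_mm)

    def axis_mm(self, ax: int) -> np.ndarray:
        """Cell-centre coordinates along an axis, mm."""
        return (np.arange(self.shape[ax]) + 0.5) * self.grid_mm

    @property
    def stable_dt_s(self) -> float:
        """Explicit-scheme stability bound dt <= h^2 * rho*c / (6k)."""
        h = self.grid_mm * 1e-3
        return h * h * self.vol_heat_capacity_J_m3K / (6.0 * self.conductivity_W_mK)


@dataclass(frozen=True)
class SourceModel:
    """Virtual transducer: Gaussian power deposition around the focus.

    ``power_gain_W_per_V2`` converts squared drive voltage to total deposited
    acoustic power; ``fwhm_mm`` is the ellipsoidal focal intensity FWHM
    (1.4 x 1.4 x 10 mm at 1.1 MHz for the modelled transducer, long axis
    along propagation).
    """

    focus_center_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    fwhm_mm: tuple[float, float, float] = (1.4, 1.4, 10.0)
    power_gain_W_per_V2: float = 250.0
    duty: float = 1.0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fwhm_mm):
            raise ValueError("fwhm_mm must be positive")
        if self.power_gain_W_per_V2 < 0:
            raise ValueError("power gain must be non-negative")
        if not (0.0 < self.duty <= 1.0):
            raise ValueError("duty must lie in (0, 1]")
        object.__setattr__(self, "focus_center_mm", tuple(float(c) for c in self.focus_center_mm))
        object.__setattr__(self, "fwhm_mm", tuple(float(f) for f in self.fwhm_mm))


@dataclass(frozen=True, eq=False)
class PlantState:
    """3-D tissue temperature rise above baseline, degC, plus elapsed time."""

    temperature_C: np.ndarray
    time_s: float = 0.0

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature_C, dtype=float)
        if not np.all(np.isfinite(T)):
            raise ValueError("temperature field contains non-finite values")
        object.__setattr__(self, "temperature_C", T)

    @classmethod
    def initial(cls, tissue: TissueParams) -> "PlantState":
        return cls(temperature_C=np.zeros(tissue.shape), time_s=0.0)


@dataclass(frozen=True)
class ScannerModel:
    """Synthetic single-slice acquisition through the plant.

    The imaging plane contains the beam axis (slice normal along y); the
    slice of ``slice_thickness_mm`` is averaged through-plane, matching a
    thick thermometry slice.  Noise is complex Gaussian per pixel, scaled so
    the phase standard deviation is ``noise_sigma_phase_rad``; drift is a
    spatially uniform phase ramp.  One integer seed plus the frame index
    makes every frame reproducible.
    """

    noise_sigma_phase_rad: float = 0.0
    drift_rate_rad_per_s: float = 0.0
    slice_center_mm: float = 6.0
    slice_thickness_mm: float = 3.0
    frame_period_s: float = 3.0
    rng_seed: int = 0
    te_s: float = 0.010
    b0_T: float = 4.7

    def __post_init__(self) -> None:
        if self.noise_sigma_phase_rad < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be positive")


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _cell_averaged_gaussian(x_mm: np.ndarray, center_mm: float, sigma_mm: float, h_mm: float) -> np.ndarray:
    """Mean of a unit Gaussian over each voxel (integral / width), 1-D."""
    from scipy.special import erf

    a = (x_mm - h_mm / 2.0 - center_mm) / (math.sqrt(2.0) * sigma_mm)
    b = (x_mm + h_mm / 2.0 - center_mm) / (math.sqrt(2.0) * sigma_mm)
    return (erf(b) - erf(a)) / 2.0


@lru_cache(maxsize=8)
def _deposition_per_watt(tissue: TissueParams, source: SourceModel) -> np.ndarray:
    """Normalized power density (W/m^3 per W total) on the plant grid.

    The separable Gaussian is integrated over each voxel rather than point
    sampled, so the deposition stays consistent under grid refinement even
    when a focal width is comparable to the spacing.
    """
    h = tissue.grid_mm
    sigmas = [f * _FWHM_TO_SIGMA for f in source.fwhm_mm]
    profiles = [
        _cell_averaged_gaussian(tissue.axis_mm(ax), source.focus_center_mm[ax], sigmas[ax], h)
        for ax in range(3)
    ]
    q = profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
    dV = (h * 1e-3) ** 3
    q /= q.sum() * dV
    return q


def _laplacian(T: np.ndarray, h_m: float) -> np.ndarray:
    """6-neighbour Laplacian with zero-flux boundaries.

    Edge padding duplicates each boundary cell, which on a cell-centred grid
    is the standard mirror ghost cell: the flux across every outer face is
    exactly zero and the stencil stays second-order.
    """
    Tp = np.pad(T, 1, mode="edge")
    lap = (
        Tp[2:, 1:-1, 1:-1]
        + Tp[:-2, 1:-1, 1:-1]
        + Tp[1:-1, 2:, 1:-1]
        + Tp[1:-1, :-2, 1:-1]
        + Tp[1:-1, 1:-1, 2:]
        + Tp[1:-1, 1:-1, :-2]
        - 6.0 * T
    )
    return lap / (h_m * h_m)


def _advance(
    state: PlantState,
    tissue: TissueParams,
    source: SourceModel,
    v_drive: float,
    dt_s: float,
) -> tuple[PlantState, np.ndarray]:
    """Step the field by dt; also return its time average over the window."""
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if state.temperature_C.shape != tissue.shape:
        raise ValueError("plant state shape does not match the tissue grid")
    n_sub = max(1, math.ceil(dt_s / tissue.stable_dt_s))
    h_sub = dt_s / n_sub
    h_m = tissue.grid_mm * 1e-3
    rc = tissue.vol_heat_capacity_J_m3K
    kappa = tissue.conductivity_W_mK / rc
    power = source.power_gain_W_per_V2 * v_drive * v_drive * source.duty
    q_C_per_s = _deposition_per_watt(tissue, source) * (power / rc)
    # Conduction and deposition are stepped explicitly; the linear perfusion
    # sink is applied as an exact exponential factor per sub-step, so a pure
    # decay matches its closed form to machine precision.
    w = tissue.perfusion_per_s
    decay = math.exp(-w * h_sub) if w > 0 else 1.0
    Ta = tissue.arterial_dT_C
    T = state.temperature_C.copy()
    avg = np.zeros_like(T)
    for _ in range(n_sub):
        T += h_sub * (kappa * _laplacian(T, h_m) + q_C_per_s)
        if w > 0:
            T = Ta + (T - Ta) * decay
        avg += T
    avg /= n_sub
    return PlantState(temperature_C=T, time_s=state.time_s + dt_s), avg


def step_plant(
    state: PlantState,
    tissue: TissueParams,
    source: SourceModel,
    v_drive: float,
    dt_s: float,
) -> PlantState:
    """Advance the bioheat field by dt under a constant drive voltage.

    Sub-steps internally whenever dt exceeds the explicit stability bound.
    With insulated boundaries and zero perfusion the total thermal energy
    grows by exactly gain * v^2 * duty * dt.
    """
    new_state, _ = _advance(state, tissue, source, v_drive, dt_s)
    return new_state


def total_energy_J(state: PlantState, tissue: TissueParams) -> float:
    """Thermal energy of the field above baseline, J (discrete bookkeeping)."""
    dV = (tissue.grid_mm * 1e-3) ** 3
    return float(state.temperature_C.sum() * tissue.vol_heat_capacity_J_m3K * dV)


def acquire_frame(
    state: PlantState,
    tissue: TissueParams,
    scanner: ScannerModel,
    thermo_cfg: ThermometryConfig,
    frame_index: int,
) -> ComplexFrame:
    """Synthesize one complex MR frame from the current plant state.

    Inverse of the thermometry chain: slice-average the field through the
    slice thickness, map degC to phase, add drift and seeded complex noise.
    Magnitude is unity inside the phantom support (the whole domain).
    """
    y = tissue.axis_mm(1)
    sel = np.abs(y - scanner.slice_center_mm) <= scanner.slice_thickness_mm / 2.0
    if not sel.any():
        raise ValueError("imaging slice does not intersect the domain")
    T2d = state.temperature_C[:, sel, :].mean(axis=1)
    scale = prf_phase_per_C(scanner.te_s, scanner.b0_T, thermo_cfg)
    phase = T2d * scale + scanner.drift_rate_rad_per_s * state.time_s
    data = np.exp(1j * phase)
    if scanner.noise_sigma_phase_rad > 0:
        rng = np.random.default_rng(scanner.rng_seed + frame_index)
        noise = scanner.noise_sigma_phase_rad * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
        data = data + noise
    fov = (tissue.domain_mm[0], tissue.domain_mm[2])
    return ComplexFrame(
        data=data,
        te_s=scanner.te_s,
        timestamp_s=state.time_s,
        b0_T=scanner.b0_T,
        fov_mm=fov,
    )


def image_pixel_mm(tissue: TissueParams) -> tuple[float, float]:
    """In-plane pixel spacing of rig frames (grid spacing along x and z)."""
    shape = (tissue.shape[0], tissue.shape[2])
    fov = (tissue.domain_mm[0], tissue.domain_mm[2])
    return (fov[0] / shape[0], fov[1] / shape[1])


def default_focus_roi(
    tissue: TissueParams,
    source: SourceModel,
    size_mm: tuple[float, float] = (2.6, 3.2),
) -> ROI:
    """Focal-mean ROI centred on the focus in the imaging plane."""
    shape = (tissue.shape[0], tissue.shape[2])
    center = (source.focus_center_mm[0], source.focus_center_mm[2])
    return ROI.from_rect(center, size_mm, image_pixel_mm(tissue), shape, label=FOCUS)


def run_virtual_sonication(
    tissue: TissueParams,
    source: SourceModel,
    scanner: ScannerModel,
    pid_params: PIDParams,
    *,
    duration_s: float,
    dose_params: DoseParams | None = None,
    dose_threshold_min: float = math.inf,
    thermo_cfg: ThermometryConfig | None = None,
    focus_roi: ROI | None = None,
    drift_roi: ROI | None = None,
    dummy_frames: int = 2,
    perfusion_schedule: Callable[[float], float] | None = None,
) -> SonicationLog:
    """Closed-loop run: plant -> frame -> controller -> drive, at the frame period.

    ``duration_s`` counts controlled frames (after the dummies and the
    baseline).  ``perfusion_schedule(t)`` optionally scales the perfusion
    coefficient over the frame interval starting at t, for disturbance
    experiments.  Deterministic for a given scanner seed.
    """
    thermo_cfg = thermo_cfg or ThermometryConfig()
    if focus_roi is None:
        focus_roi = default_focus_roi(tissue, source)
    period = scanner.frame_period_s
    n_frames = dummy_frames + 1 + int(round(duration_s / period))
    v_cmd = [0.0]
    state = PlantState.initial(tissue)

    def frames():
        # The acquisition integrates over the whole frame period, so each
        # frame encodes the window-averaged field rather than a snapshot.
        nonlocal state
        for k in range(n_frames):
            if k > 0:
                tis = tissue
                if perfusion_schedule is not None:
                    factor = perfusion_schedule(state.time_s)
                    tis = replace(
                        tissue, perfusion_per_s=tissue.perfusion_per_s * factor
                    )
                state, window_avg = _advance(state, tis, source, v_cmd[0], period)
                seen = PlantState(temperature_C=window_avg, time_s=state.time_s)
            else:
                seen = state
            yield acquire_frame(seen, tissue, scanner, thermo_cfg, k)

    def sink(v: float) -> None:
        v_cmd[0] = v

    return run_treatment(
        frames(),
        focus_roi,
        pid_params,
        dose_params=dose_params,
        dose_threshold_min=dose_threshold_min,
        thermo_cfg=thermo_cfg,
        drift_roi=drift_roi,
        output_sink=sink,
        dummy_frames=dummy_frames,
    )
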