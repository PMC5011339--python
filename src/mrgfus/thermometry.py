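"""Baseline-subtracted PRF-shift MR thermometry.

The water proton resonance frequency falls linearly with temperature at about
-0.01 ppm/degC, so a temperature rise shows up as a phase shift between two
gradient-echo images:

    dT = dphi / (2*pi * gamma * alpha * B0 * TE)

with gamma the gyromagnetic ratio (Hz/T), alpha the PRF thermal coefficient
(1/degC, negative), B0 the static field (T), and TE the echo time (s).  Phase
differences are taken through the complex-conjugate product, which is immune
to each frame's absolute phase offset and avoids spurious wraps that plain
angle subtraction would introduce.  Slow scanner field drift is removed by
subtracting the apparent temperature in an unheated reference region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Gyromagnetic ratio of the water proton, Hz/T.
GYROMAGNETIC_RATIO_HZ_PER_T = 42.576e6

#: Conventional PRF thermal coefficient, ppm/degC.
PRF_COEFFICIENT_PPM_PER_C = -0.01


@dataclass(frozen=True, eq=False)
class ComplexFrame:
    """One timestamped complex MR slice plus acquisition metadata.

    Parameters
    ----------
    data : ndarray of complex, shape (nx, ny)
        Complex image; magnitude in arbitrary units, phase in radians.
    te_s : float
        Echo time in seconds (> 0).
    timestamp_s : float
        Acquisition time relative to the first frame, seconds.
    b0_T : float
        Static field strength in tesla (> 0).
    fov_mm : tuple of float
        In-plane field of view (mm along each image axis).
    """

    data: np.ndarray
    te_s: float
    timestamp_s: float
    b0_T: float
    fov_mm: tuple[float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError(f"frame data must be 2-D, got shape {data.shape}")
        if not np.all(np.isfinite(data.real)) or not np.all(np.isfinite(data.imag)):
            raise ValueError("frame data contains non-finite values")
        if self.te_s <= 0:
            raise ValueError(f"te_s must be positive, got {self.te_s}")
        if self.b0_T <= 0:
            raise ValueError(f"b0_T must be positive, got {self.b0_T}")
        if len(self.fov_mm) != 2 or any(f <= 0 for f in self.fov_mm):
            raise ValueError(f"fov_mm must be two positive extents, got {self.fov_mm}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "fov_mm", tuple(float(f) for f in self.fov_mm))

    @property
    def matrix(self) -> tuple[int, int]:
        """In-plane sample counts (matches ``data.shape``)."""
        return self.data.shape

    @property
    def pixel_mm(self) -> tuple[float, float]:
        """In-plane pixel spacing, mm."""
        return (self.fov_mm[0] / self.data.shape[0], self.fov_mm[1] / self.data.shape[1])


@dataclass(frozen=True)
class ThermometryConfig:
    """PRF reconstruction constants and options.

    alpha and gamma are the standard literature values; both are overridable.
    ``magnitude_floor_frac`` flags pixels whose baseline magnitude falls below
    this fraction of the image's 95th-percentile magnitude (air/noise pixels
    that would otherwise show apparent elevated temperatures).
    """

    alpha_ppm_per_C: float = PRF_COEFFICIENT_PPM_PER_C
    gamma_Hz_per_T: float = GYROMAGNETIC_RATIO_HZ_PER_T
    unwrap_enabled: bool = False
    magnitude_floor_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.alpha_ppm_per_C >= 0:
            raise ValueError("alpha_ppm_per_C must be negative")
        if self.gamma_Hz_per_T <= 0:
            raise ValueError("gamma_Hz_per_T must be positive")


@dataclass(frozen=True, eq=False)
class TemperatureMap:
    """Per-pixel temperature change from baseline, degC, with validity mask."""

    delta_T_C: np.ndarray
    mask: np.ndarray
    timestamp_s: float

    def __post_init__(self) -> None:
        dT = np.asarray(self.delta_T_C, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if dT.shape != mask.shape:
            raise ValueError("delta_T_C and mask shapes differ")
        if not np.all(np.isfinite(dT[mask])):
            raise ValueError("non-finite temperature inside validity mask")
        object.__setattr__(self, "delta_T_C", dT)
        object.__setattr__(self, "mask", mask)


FOCUS = "focus"
DRIFT_REFERENCE = "drift-reference"


@dataclass(frozen=True, eq=False)
class ROI:
    """A 2-D boolean region tagged with its role (focus or drift-reference)."""

    mask: np.ndarray
    label: str = FOCUS

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not mask.any():
            raise ValueError("ROI mask has no true pixels")
        if self.label not in (FOCUS, DRIFT_REFERENCE):
            raise ValueError(f"unknown ROI label {self.label!r}")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_rect(
        cls,
        center_mm: tuple[float, float],
        size_mm: tuple[float, float],
        pixel_mm: tuple[float, float],
        shape: tuple[int, int],
        label: str = FOCUS,
    ) -> "ROI":
        """Build a rectangular ROI from mm coordinates.

        Sizes are rounded to the nearest whole pixel count (minimum 1); the
        mm origin sits at the corner of the image, pixel i spanning
        [i*px, (i+1)*px).
        """
        mask = np.zeros(shape, dtype=bool)
        slices = []
        for ax in range(2):
            px = pixel_mm[ax]
            n = max(1, round(size_mm[ax] / px))
            c = int(round(center_mm[ax] / px - 0.5))
            start = max(0, c - n // 2)
            stop = min(shape[ax], start + n)
            if stop <= start:
                raise ValueError("rectangular ROI falls outside the image")
            slices.append(slice(start, stop))
        mask[slices[0], slices[1]] = True
        return cls(mask=mask, label=label)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def prf_phase_per_C(te_s: float, b0_T: float, cfg: ThermometryConfig) -> float:
    """Phase shift per degC of heating, rad/degC (negative for alpha < 0)."""
    if te_s <= 0 or b0_T <= 0:
        raise ValueError("te_s and b0_T must be positive")
    return 2.0 * np.pi * cfg.gamma_Hz_per_T * cfg.alpha_ppm_per_C * 1e-6 * b0_T * te_s


def phase_difference(current: ComplexFrame, baseline: ComplexFrame) -> np.ndarray:
    """Wrapped phase difference current - baseline, in (-pi, pi].

    Computed as the angle of ``current * conj(baseline)`` so each frame's
    absolute phase offset cancels.
    """
    if current.data.shape != baseline.data.shape:
        raise ValueError(
            f"frame shape mismatch: {current.data.shape} vs {baseline.data.shape}"
        )
    if current.te_s != baseline.te_s or current.b0_T != baseline.b0_T:
        raise ValueError("frames differ in te_s or b0_T; cannot subtract phases")
    return np.angle(current.data * np.conj(baseline.data))


def temporal_unwrap(dphi: np.ndarray, prev_dphi: np.ndarray) -> np.ndarray:
    """Add the multiple of 2*pi bringing each pixel within pi of its previous value."""
    two_pi = 2.0 * np.pi
    return dphi + two_pi * np.round((prev_dphi - dphi) / two_pi)


def phase_to_temperature(
    dphi: np.ndarray,
    frame: ComplexFrame,
    cfg: ThermometryConfig,
    baseline: ComplexFrame | None = None,
) -> TemperatureMap:
    """Convert a phase-difference map to a temperature-change map.

    The validity mask flags pixels whose baseline magnitude falls below
    ``cfg.magnitude_floor_frac`` of the 95th-percentile magnitude; with no
    baseline supplied every pixel is considered valid.
    """
    dphi = np.asarray(dphi, dtype=float)
    if not np.all(np.isfinite(dphi)):
        raise ValueError("phase map contains non-finite values")
    scale = prf_phase_per_C(frame.te_s, frame.b0_T, cfg)
    delta_T = dphi / scale
    if baseline is not None:
        mag = np.abs(baseline.data)
        floor = cfg.magnitude_floor_frac * np.percentile(mag, 95)
        mask = mag >= floor
    else:
        mask = np.ones_like(delta_T, dtype=bool)
    return TemperatureMap(delta_T_C=delta_T, mask=mask, timestamp_s=frame.timestamp_s)


def compute_temperature_map(
    current: ComplexFrame,
    baseline: ComplexFrame,
    cfg: ThermometryConfig,
    prev_dphi: np.ndarray | None = None,
) -> tuple[TemperatureMap, np.ndarray]:
    """Full per-frame reconstruction: phase difference -> (optional unwrap) -> degC.

    Returns the map together with the (possibly unwrapped) phase difference so
    the caller can thread it into the next frame when temporal unwrapping is
    enabled.
    """
    dphi = phase_difference(current, baseline)
    if cfg.unwrap_enabled and prev_dphi is not None:
        dphi = temporal_unwrap(dphi, prev_dphi)
    tmap = phase_to_temperature(dphi, current, cfg, baseline=baseline)
    return tmap, dphi


def drift_correct(tmap: TemperatureMap, ref: ROI) -> TemperatureMap:
    """Subtract the mean temperature over an unheated reference ROI.

    Removes spatially uniform scanner field drift exactly; the corrected map
    averages zero over the reference region.
    """
    if ref.label != DRIFT_REFERENCE:
        raise ValueError(f"drift correction requires a {DRIFT_REFERENCE!r} ROI, got {ref.label!r}")
    if ref.mask.shape != tmap.delta_T_C.shape:
        raise ValueError("reference ROI shape does not match the temperature map")
    effective = ref.mask & tmap.mask
    if not effective.any():
        raise ValueError("drift-reference ROI has no valid pixels")
    offset = float(tmap.delta_T_C[effective].mean())
    return replace(tmap, delta_T_C=tmap.delta_T_C - offset)


def roi_mean(tmap: TemperatureMap, roi: ROI) -> float:
    """Arithmetic mean of the temperature change over the valid pixels of a ROI."""
    if roi.mask.shape != tmap.delta_T_C.shape:
        raise ValueError("ROI shape does not match the temperature map")
    effective = roi.mask & tmap.mask
    if not effective.any():
        raise ValueError("ROI has no valid pixels")
    return float(tmap.delta_T_C[effective].mean())
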