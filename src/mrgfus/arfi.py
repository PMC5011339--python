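"""MR acoustic radiation force imaging (MR-ARFI) reconstruction.

A bipolar motion-encoding gradient (MEG) makes image phase proportional to
tissue displacement along the encoding axis.  Two acquisitions with opposite
MEG polarity are subtracted, and residual eddy-current phase is removed by
also subtracting, per polarity, an acquisition with the ultrasound off:

    dphi = (phi[+, on] - phi[+, off]) - (phi[-, on] - phi[-, off])
    dx   = dphi / (2 * gamma * G * l)

with gamma the gyromagnetic ratio in rad/(s*T), G the gradient lobe
amplitude (T/m) and l the single-lobe duration (s); the lobe is approximated
as a rectangle, which is accurate for trapezoids with sharp rises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Angular gyromagnetic ratio, rad/(s*T).
GAMMA_RAD_PER_S_T = 2.0 * np.pi * 42.576e6


def _wrap(phi: np.ndarray) -> np.ndarray:
    """Wrap phases to (-pi, pi]."""
    return np.angle(np.exp(1j * phi))


@dataclass(frozen=True)
class MEGParams:
    """Bipolar motion-encoding gradient parameters.

    Defaults correspond to a 10 G/cm lobe of 4 ms (the single-lobe duration
    of an 8 ms bipolar pair).
    """

    g_strength_T_per_m: float = 0.10
    lobe_duration_s: float = 4e-3
    gamma_rad_per_sT: float = GAMMA_RAD_PER_S_T

    def __post_init__(self) -> None:
        if self.g_strength_T_per_m <= 0:
            raise ValueError("g_strength_T_per_m must be positive")
        if self.lobe_duration_s <= 0:
            raise ValueError("lobe_duration_s must be positive")
        if self.gamma_rad_per_sT <= 0:
            raise ValueError("gamma_rad_per_sT must be positive")

    @classmethod
    def from_scanner_units(
        cls, g_amp_G_per_cm: float, g_dur_ms: float, **kwargs
    ) -> "MEGParams":
        """Build from scanner-console units (gauss/cm and ms)."""
        return cls(
            g_strength_T_per_m=g_amp_G_per_cm * 1e-4 / 1e-2,
            lobe_duration_s=g_dur_ms * 1e-3,
            **kwargs,
        )


@dataclass(frozen=True, eq=False)
class ArfiFrameSet:
    """Four phase images: (+/- MEG polarity) x (FUS on/off), radians."""

    phase_plus_on: np.ndarray
    phase_plus_off: np.ndarray
    phase_minus_on: np.ndarray
    phase_minus_off: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        shape = None
        for name in (
            "phase_plus_on",
            "phase_plus_off",
            "phase_minus_on",
            "phase_minus_off",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("ARFI phase images must share one shape")
            arrays[name] = arr
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)


@dataclass(frozen=True, eq=False)
class DisplacementMap:
    """Per-pixel displacement along the encoding axis, metres, signed."""

    dx_m: np.ndarray
    encoding_axis: str = "propagation"

    def __post_init__(self) -> None:
        object.__setattr__(self, "dx_m", np.asarray(self.dx_m, dtype=float))


def eddy_current_correct(frames: ArfiFrameSet) -> tuple[np.ndarray, np.ndarray]:
    """Per polarity, subtract the FUS-off phase from the FUS-on phase.

    Eddy-current phase is common to the on/off pair at each polarity and
    cancels exactly; results are wrapped to (-pi, pi].
    """
    dphi_plus = _wrap(frames.phase_plus_on - frames.phase_plus_off)
    dphi_minus = _wrap(frames.phase_minus_on - frames.phase_minus_off)
    return dphi_plus, dphi_minus


def displacement_from_phase(
    dphi_plus: np.ndarray, dphi_minus: np.ndarray, meg: MEGParams
) -> DisplacementMap:
    """Scale the polarity phase difference to displacement."""
    dphi_plus = np.asarray(dphi_plus, dtype=float)
    dphi_minus = np.asarray(dphi_minus, dtype=float)
    if dphi_plus.shape != dphi_minus.shape:
        raise ValueError("polarity phase maps must share one shape")
    dphi = _wrap(dphi_plus - dphi_minus)
    dx = dphi / (2.0 * meg.gamma_rad_per_sT * meg.g_strength_T_per_m * meg.lobe_duration_s)
    return DisplacementMap(dx_m=dx)


def reconstruct_displacement(frames: ArfiFrameSet, meg: MEGParams) -> DisplacementMap:
    """Full pipeline: eddy-current correction then displacement scaling."""
    dphi_plus, dphi_minus = eddy_current_correct(frames)
    return displacement_from_phase(dphi_plus, dphi_minus, meg)


def _profile_fwhm_px(profile: np.ndarray, peak_idx: int) -> float:
    """FWHM of a 1-D profile, in pixels, by linear interpolation at half max."""
    peak = profile[peak_idx]
    half = peak / 2.0
    n = profile.size
    # walk left
    i = peak_idx
    while i > 0 and profile[i - 1] >= half:
        i -= 1
    if i == 0:
        raise ValueError("half-maximum crossing not found left of the peak")
    frac = (profile[i] - half) / (profile[i] - profile[i - 1])
    left = i - frac
    # walk right
    j = peak_idx
    while j < n - 1 and profile[j + 1] >= half:
        j += 1
    if j == n - 1:
        raise ValueError("half-maximum crossing not found right of the peak")
    frac = (profile[j] - half) / (profile[j] - profile[j + 1])
    right = j + frac
    return right - left


def focal_spot_metrics(
    dmap: DisplacementMap, pixel_mm: tuple[float, float]
) -> tuple[float, float]:
    """Peak displacement (m) and FWHM (mm) of the focal spot.

    The map median is subtracted as a background estimate; the FWHM is the
    mean of the half-maximum widths of the two 1-D profiles through the peak
    pixel, each read by linear interpolation between the crossings.
    """
    dx = dmap.dx_m - np.median(dmap.dx_m)
    if not np.any(dx > 0) or np.ptp(dx) == 0:
        raise ValueError("displacement map has no positive peak")
    peak_idx = np.unravel_index(np.argmax(dx), dx.shape)
    peak = float(dmap.dx_m[peak_idx])
    widths = []
    for ax in range(2):
        profile = dx[:, peak_idx[1]] if ax == 0 else dx[peak_idx[0], :]
        widths.append(_profile_fwhm_px(profile, peak_idx[ax]) * pixel_mm[ax])
    return peak, float(np.mean(widths))
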