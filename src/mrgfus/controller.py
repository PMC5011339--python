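"""Constrained PID control and the real-time treatment loop.

The focal temperature error e = setpoint - measured drives the commanded
transducer voltage through a clamped PID law

    v = clip( Kp*e + Ki * integral(e dt) + Kd * de/dt, 0, v_max )

discretized at the imaging frame period with a rectangle-rule integral and
backward-difference derivative.  The upper clamp keeps the acoustic pressure
below the cavitation / skin-burn threshold; the lower clamp at 0 V reflects
that negative drive is physically meaningless.  Anti-windup is by conditional
integration: the integral freezes while the output is clamped and the error
would push it further into saturation.

``run_treatment`` orchestrates the loop over a stream of complex frames:
skip dummy frames, take the first retained frame as baseline, then per frame
reconstruct temperature, update CEM43 dose, step the PID, apply the dose
shut-off, and emit the voltage.  Whatever happens, the final emitted voltage
is zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .dosimetry import DoseAccumulator, DoseParams, update_dose
from .thermometry import (
    ROI,
    ComplexFrame,
    ThermometryConfig,
    compute_temperature_map,
    drift_correct,
    roi_mean,
)

logger = logging.getLogger(__name__)

#: Hand-tuned gains from a graphite-agar phantom, and the in vivo voltage clamp.
DEFAULT_KP = 1e-3
DEFAULT_KI = 1e-5
DEFAULT_KD = 5e-3
DEFAULT_V_MAX = 0.070


@dataclass(frozen=True)
class PIDParams:
    """Controller gains, output clamp, and temperature-rise set point.

    Units: kp V/degC, ki V/(degC*s), kd V*s/degC, v_max V (peak-to-peak at
    the generator output, pre-amplifier), setpoint_C degC above baseline.
    """

    setpoint_C: float
    kp: float = DEFAULT_KP
    ki: float = DEFAULT_KI
    kd: float = DEFAULT_KD
    v_max: float = DEFAULT_V_MAX

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0 or self.kd < 0:
            raise ValueError("gains must be non-negative")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")


@dataclass(frozen=True)
class PIDState:
    """Controller memory between frames.

    The full error history enters only through the running integral plus the
    last error; ``prev_error_C`` is None before the first update so the first
    derivative is zero.
    """

    integral_Cs: float = 0.0
    prev_error_C: float | None = None
    prev_time_s: float = 0.0
    last_v_out: float = 0.0


def pid_step(
    state: PIDState,
    params: PIDParams,
    measured_dT_C: float,
    t_s: float,
) -> tuple[float, PIDState]:
    """One discrete PID update; returns (clamped voltage, new state).

    A non-finite measurement retains the previous output and leaves the
    state unchanged.  Non-monotonic time is rejected.
    """
    if not math.isfinite(measured_dT_C):
        logger.warning("non-finite focal temperature at t=%.3f s; holding v_out", t_s)
        return state.last_v_out, state
    dt = t_s - state.prev_time_s
    if dt <= 0:
        raise ValueError(f"non-monotonic time: t={t_s} after t={state.prev_time_s}")
    e = params.setpoint_C - measured_dT_C
    deriv = 0.0 if state.prev_error_C is None else (e - state.prev_error_C) / dt
    integral = state.integral_Cs + e * dt
    raw = params.kp * e + params.ki * integral + params.kd * deriv
    # Conditional integration: do not wind up while saturated in the error's
    # own direction.
    if (raw > params.v_max and e > 0) or (raw < 0.0 and e < 0):
        integral = state.integral_Cs
        raw = params.kp * e + params.ki * integral + params.kd * deriv
    v_out = min(max(raw, 0.0), params.v_max)
    return v_out, PIDState(
        integral_Cs=integral, prev_error_C=e, prev_time_s=t_s, last_v_out=v_out
    )


def apply_dose_shutoff(v_out: float, acc: DoseAccumulator) -> float:
    """Zero the commanded voltage once the dose threshold has latched."""
    return 0.0 if acc.reached else v_out


@dataclass
class SonicationLog:
    """Per-frame treatment record with strictly increasing timestamps."""

    records: list[dict] = field(default_factory=list)

    COLUMNS = ("timestamp_s", "focal_mean_C", "v_out", "cem43_min", "shutoff_flag")

    def append(
        self,
        timestamp_s: float,
        focal_mean_C: float,
        v_out: float,
        cem43_min: float,
        shutoff_flag: bool,
    ) -> None:
        if self.records and timestamp_s <= self.records[-1]["timestamp_s"]:
            raise ValueError("log timestamps must be strictly increasing")
        self.records.append(
            {
                "timestamp_s": float(timestamp_s),
                "focal_mean_C": float(focal_mean_C),
                "v_out": float(v_out),
                "cem43_min": float(cem43_min),
                "shutoff_flag": bool(shutoff_flag),
            }
        )

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=list(self.COLUMNS))

    @property
    def timestamps_s(self) -> np.ndarray:
        return np.array([r["timestamp_s"] for r in self.records])

    @property
    def focal_mean_C(self) -> np.ndarray:
        return np.array([r["focal_mean_C"] for r in self.records])

    @property
    def v_out(self) -> np.ndarray:
        return np.array([r["v_out"] for r in self.records])


def run_treatment(
    frame_source: Iterable[ComplexFrame],
    focus_roi: ROI,
    pid_params: PIDParams,
    *,
    dose_params: DoseParams | None = None,
    dose_threshold_min: float = math.inf,
    thermo_cfg: ThermometryConfig | None = None,
    drift_roi: ROI | None = None,
    output_sink: Callable[[float], None] | None = None,
    dummy_frames: int = 2,
) -> SonicationLog:
    """Run the closed-loop treatment over a stream of complex frames.

    Per retained frame: phase difference against the baseline -> temperature
    map -> optional drift correction -> focal mean -> dose update -> PID ->
    dose shut-off -> emit voltage.  On stream end or any failure a final zero
    voltage is emitted (then the log is returned, or the exception
    propagates).
    """
    thermo_cfg = thermo_cfg or ThermometryConfig()
    dose_params = dose_params or DoseParams()
    sink = output_sink if output_sink is not None else (lambda v: None)
    log = SonicationLog()
    it = iter(frame_source)
    try:
        try:
            for _ in range(dummy_frames):
                next(it)
            baseline = next(it)
        except StopIteration:
            raise ValueError(
                f"frame stream ended before baseline (need >= {dummy_frames + 2} frames)"
            ) from None
        acc = DoseAccumulator(threshold_min=dose_threshold_min)
        pid_state = PIDState(prev_time_s=baseline.timestamp_s)
        prev_t = baseline.timestamp_s
        prev_dphi: np.ndarray | None = None
        v = 0.0
        for frame in it:
            tmap, prev_dphi = compute_temperature_map(
                frame, baseline, thermo_cfg, prev_dphi=prev_dphi
            )
            if drift_roi is not None:
                tmap = drift_correct(tmap, drift_roi)
            focal = roi_mean(tmap, focus_roi)
            dt = frame.timestamp_s - prev_t
            acc = update_dose(acc, focal, dt, dose_params)
            v, pid_state = pid_step(pid_state, pid_params, focal, frame.timestamp_s)
            v_cmd = apply_dose_shutoff(v, acc)
            sink(v_cmd)
            log.append(
                timestamp_s=frame.timestamp_s,
                focal_mean_C=focal,
                v_out=v_cmd,
                cem43_min=acc.cem43_min,
                shutoff_flag=acc.reached,
            )
            prev_t = frame.timestamp_s
        return log
    finally:
        # Fail-safe: whatever happened above, the generator ends at 0 V.
        sink(0.0)
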