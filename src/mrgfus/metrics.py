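"""Closed-loop performance metrics.

The initial rise is defined as the point at which the measured focal mean
first crosses the set point; overshoot and steady-state precision/accuracy
are computed over the frames from that crossing onward, matching how
controlled-sonication performance is conventionally reported.
"""

from __future__ import annotations

import numpy as np

from .controller import SonicationLog


def first_crossing_index(focal_mean_C: np.ndarray, setpoint_C: float) -> int | None:
    """Index of the first frame at or above the set point, or None."""
    above = np.asarray(focal_mean_C) >= setpoint_C
    if not above.any():
        return None
    return int(np.argmax(above))


def initial_overshoot(log: SonicationLog, setpoint_C: float) -> float:
    """Maximum excursion above the set point after the first crossing, degC."""
    focal = log.focal_mean_C
    idx = first_crossing_index(focal, setpoint_C)
    if idx is None:
        raise ValueError("focal mean never crossed the set point")
    return float(focal[idx:].max() - setpoint_C)


def post_rise_stats(log: SonicationLog, setpoint_C: float) -> dict[str, float]:
    """Std and RMSE of (focal mean - setpoint) after the first crossing."""
    focal = log.focal_mean_C
    idx = first_crossing_index(focal, setpoint_C)
    if idx is None:
        raise ValueError("focal mean never crossed the set point")
    err = focal[idx:] - setpoint_C
    return {
        "std_C": float(err.std(ddof=0)),
        "rmse_C": float(np.sqrt(np.mean(err**2))),
        "n_frames": int(err.size),
    }
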