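"""Reference closed-loop experiments on the virtual rig.

Two protocols mirror the validation studies a bench system would run:

* ``setpoint_sweep`` — repeated 10-min sonications on the agar phantom at
  temperature-rise set points between 2 and 10 degC, fixed PID gains,
  reporting initial overshoot and post-rise precision/accuracy per run.
* ``disturbance_runs`` — a 12-min sonication on the perfused mouse-tumor
  preset at +6 degC with three 30 s perfusion-doubling disturbances
  (emulating breathing-rate changes), reporting post-rise RMSE and whether
  the controller visibly raised the voltage at each disturbance.

Runs whose focal mean never crosses the set point have no defined post-rise
window; they are dropped from ensemble statistics and counted in the
``crossed`` column (none occur at the shipped defaults).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .controller import PIDParams
from .metrics import first_crossing_index, initial_overshoot, post_rise_stats
from .presets import load_preset, with_seed
from .rig import default_focus_roi, run_virtual_sonication

DEFAULT_SETPOINTS_C = (2.0, 4.0, 6.0, 8.0, 10.0)
DISTURBANCE_TIMES_S = (240.0, 420.0, 600.0)
DISTURBANCE_DURATION_S = 30.0


def run_setpoint_trial(
    setpoint_C: float,
    seed: int,
    duration_s: float = 600.0,
    preset_name: str = "agar-phantom",
) -> dict:
    """One closed-loop phantom sonication; returns per-run metrics."""
    preset = with_seed(load_preset(preset_name), seed)
    log = run_virtual_sonication(
        preset.tissue,
        preset.source,
        preset.scanner,
        PIDParams(setpoint_C=setpoint_C),
        duration_s=duration_s,
        dose_params=preset.dose_params,
        focus_roi=preset.focus_roi,
        dummy_frames=preset.dummy_frames,
    )
    row = {"setpoint_C": setpoint_C, "seed": seed, "crossed": False}
    if first_crossing_index(log.focal_mean_C, setpoint_C) is not None:
        stats = post_rise_stats(log, setpoint_C)
        row.update(
            crossed=True,
            overshoot_C=initial_overshoot(log, setpoint_C),
            std_C=stats["std_C"],
            rmse_C=stats["rmse_C"],
            n_frames=len(log),
        )
    return row


def setpoint_sweep(
    seeds: Iterable[int],
    setpoints_C: Sequence[float] = DEFAULT_SETPOINTS_C,
    duration_s: float = 600.0,
    preset_name: str = "agar-phantom",
) -> pd.DataFrame:
    """Run the full set-point x seed ensemble; one row per run."""
    rows = [
        run_setpoint_trial(sp, seed, duration_s=duration_s, preset_name=preset_name)
        for sp in setpoints_C
        for seed in seeds
    ]
    return pd.DataFrame(rows)


def sweep_summary(sweep: pd.DataFrame) -> dict[str, float]:
    """Ensemble means: overshoot at low set points and at 10 degC, precision, RMSE."""
    ok = sweep[sweep["crossed"]]
    low = ok[ok["setpoint_C"] < 10.0]
    high = ok[ok["setpoint_C"] == 10.0]
    return {
        "overshoot_low_C": float(low["overshoot_C"].mean()),
        "overshoot_10C_C": float(high["overshoot_C"].mean()) if len(high) else float("nan"),
        "mean_std_C": float(ok["std_C"].mean()),
        "mean_rmse_C": float(ok["rmse_C"].mean()),
        "n_runs": int(len(sweep)),
        "n_crossed": int(len(ok)),
    }


def perfusion_disturbance_schedule(
    times_s: Sequence[float] = DISTURBANCE_TIMES_S,
    duration_s: float = DISTURBANCE_DURATION_S,
    factor: float = 2.0,
):
    """Perfusion multiplier: ``factor`` inside each disturbance window, else 1."""

    def schedule(t: float) -> float:
        return factor if any(t0 <= t < t0 + duration_s for t0 in times_s) else 1.0

    return schedule


def run_disturbance_trial(
    seed: int,
    setpoint_C: float = 6.0,
    duration_s: float = 720.0,
    preset_name: str = "mouse-tumor",
    times_s: Sequence[float] = DISTURBANCE_TIMES_S,
) -> dict:
    """One disturbance-rejection sonication on the perfused preset."""
    preset = with_seed(load_preset(preset_name), seed)
    log = run_virtual_sonication(
        preset.tissue,
        preset.source,
        preset.scanner,
        PIDParams(setpoint_C=setpoint_C),
        duration_s=duration_s,
        dose_params=preset.dose_params,
        focus_roi=preset.focus_roi,
        dummy_frames=preset.dummy_frames,
        perfusion_schedule=perfusion_disturbance_schedule(times_s),
    )
    t, f, v = log.timestamps_s, log.focal_mean_C, log.v_out
    row = {"seed": seed, "crossed": False}
    if first_crossing_index(f, setpoint_C) is not None:
        stats = post_rise_stats(log, setpoint_C)
        dips, v_rises = [], []
        for t0 in times_s:
            during = (t >= t0) & (t < t0 + 60.0)
            before = (t >= t0 - 60.0) & (t < t0)
            dips.append(setpoint_C - float(f[during].min()))
            v_rises.append(float(v[during].mean()) > float(v[before].mean()))
        row.update(
            crossed=True,
            rmse_C=stats["rmse_C"],
            std_C=stats["std_C"],
            max_dip_C=max(dips),
            voltage_rises=all(v_rises),
            n_frames=len(log),
        )
    return row


def disturbance_runs(seeds: Iterable[int], **kwargs) -> pd.DataFrame:
    return pd.DataFrame([run_disturbance_trial(seed, **kwargs) for seed in seeds])
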