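"""CEM43 thermal-dose accounting.

Thermal dose is expressed as cumulative equivalent minutes at 43 degC: an
interval dt at absolute temperature T contributes R^(43 - T) * dt minutes,
with R = 0.5 above the 43 degC breakpoint and R = 0.25 below it
(Sapareto-Dewey convention).  The accumulator latches a completion flag once
a configured dose threshold is reached; the treatment loop uses that flag to
silence the transducer output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoseParams:
    """CEM43 rate constants.

    ``baseline_body_C`` maps a measured temperature *rise* to absolute
    temperature: 37 degC in vivo (so a +6 degC rise sits at the 43 degC
    breakpoint); phantom runs may set it to ambient.
    """

    r_above: float = 0.5
    r_below: float = 0.25
    t_break_C: float = 43.0
    baseline_body_C: float = 37.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_below <= self.r_above < 1.0):
            raise ValueError(
                f"require 0 < r_below <= r_above < 1, got {self.r_below}, {self.r_above}"
            )


@dataclass(frozen=True)
class DoseAccumulator:
    """Running CEM43 equivalent minutes with a latched shut-off flag."""

    cem43_min: float = 0.0
    threshold_min: float = math.inf
    reached: bool = False

    def __post_init__(self) -> None:
        if self.cem43_min < 0:
            raise ValueError("cem43_min must be non-negative")


def dose_rate_equiv_min_per_min(T_abs_C: float, params: DoseParams) -> float:
    """Equivalent minutes at 43 degC accrued per minute at absolute T."""
    r = params.r_above if T_abs_C >= params.t_break_C else params.r_below
    return r ** (params.t_break_C - T_abs_C)


def update_dose(
    acc: DoseAccumulator,
    focal_dT_C: float,
    dt_s: float,
    params: DoseParams,
) -> DoseAccumulator:
    """Advance the accumulator by one interval at the measured focal rise.

    Non-finite temperatures skip the frame (accumulator unchanged, event
    logged); the dose is non-decreasing and the flag never reverts.
    """
    if dt_s <= 0:
        raise ValueError(f"dt_s must be positive, got {dt_s}")
    if not math.isfinite(focal_dT_C):
        logger.warning("non-finite focal temperature; dose frame skipped")
        return acc
    T_abs = params.baseline_body_C + focal_dT_C
    increment = dose_rate_equiv_min_per_min(T_abs, params) * dt_s / 60.0
    cem = acc.cem43_min + increment
    return replace(acc, cem43_min=cem, reached=acc.reached or cem >= acc.threshold_min)
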