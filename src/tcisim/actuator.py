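"""Infusion-pump actuator: delivery constraints, reservoir, alarms.

The actuator stands between the controller and the patient: whatever rate the
controller requests, what is actually delivered respects the device and
physiological limits — non-negative, quantized to the pump's rate resolution,
capped at the maximum allowed rate, and zero once the syringe is empty.
Constraint violations raise flags that end up in the trial event log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ActuatorConfig", "constrain_rate", "deplete"]

# alarm / event flags
SATURATED = "SATURATED"
LOW_RESERVOIR = "LOW_RESERVOIR"
EMPTY = "EMPTY"
NEGATIVE_REQUEST = "NEGATIVE_REQUEST"


@dataclass(frozen=True)
class ActuatorConfig:
    """Delivery-device limits.

    max_rate : physiological/device maximum delivery rate, mg/min (required,
        scenario-specific — there is no universal safe default)
    min_rate_step : rate quantization, mg/min; 0 means continuous
    syringe_volume : drug initially available in the syringe, mg
    low_reservoir_fraction : remaining fraction below which the low-reservoir
        alarm is raised
    """

    max_rate: float
    min_rate_step: float = 0.0
    syringe_volume: float = float("inf")
    low_reservoir_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.max_rate <= 0:
            raise ValueError("max_rate must be positive")
        if self.min_rate_step < 0:
            raise ValueError("min_rate_step must be >= 0")
        if not 0.0 <= self.low_reservoir_fraction < 1.0:
            raise ValueError("low_reservoir_fraction must be in [0, 1)")
        if self.syringe_volume <= 0:
            raise ValueError("syringe_volume must be positive")


def constrain_rate(
    requested: float, cfg: ActuatorConfig, reservoir: float
) -> tuple[float, set[str]]:
    """Map a requested rate to the rate actually deliverable.

    Returns ``(actual, flags)`` with actual = clip(quantize(requested),
    0, max_rate), forced to 0 when the reservoir is exhausted.
    """
    if not np.isfinite(requested):
        raise ValueError("requested rate must be finite")
    flags: set[str] = set()
    if requested < 0:
        flags.add(NEGATIVE_REQUEST)
        requested = 0.0
    if cfg.min_rate_step > 0:
        requested = round(requested / cfg.min_rate_step) * cfg.min_rate_step
    actual = min(requested, cfg.max_rate)
    if actual < requested:
        flags.add(SATURATED)
    if reservoir <= 0:
        actual = 0.0
        flags.add(EMPTY)
    elif (
        np.isfinite(cfg.syringe_volume)
        and reservoir / cfg.syringe_volume < cfg.low_reservoir_fraction
    ):
        flags.add(LOW_RESERVOIR)
    return actual, flags


def deplete(reservoir: float, rate: float, dt: float) -> tuple[float, float]:
    """Advance the reservoir by one delivery interval.

    Returns ``(new_reservoir, delivered)``; delivery is truncated when the
    reservoir holds less than rate*dt.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    wanted = rate * dt
    delivered = min(wanted, max(reservoir, 0.0))
    return reservoir - delivered, delivered
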