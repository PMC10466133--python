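"""Plasma-concentration sensor emulation.

A real concentration sensor departs from the true plasma level in three ways:
noise (the combined residual-error model of the population module), a finite
measurement period (time between consecutive samples t_n - t_{n-1}), and a
measurement delay tau (the time a sample needs before its value is usable by
the controller).  On top of the in-distribution noise, occasional failures
produce readings outside the noise statistics (spikes, dropouts, stuck
values); these are off by default.

Times in this module are expressed in minutes internally; configuration
surfaces accept seconds and convert on load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pk import CompartmentTrajectory, PKParameters
from .population import PopulationModel, apply_residual_error

__all__ = ["MeasurementSchedule", "Measurement", "FailureModel", "sample_measurements"]

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class MeasurementSchedule:
    """Sampling cadence: all fields in minutes."""

    period: float  # t_n - t_{n-1}
    delay: float = 0.0  # tau: sample at t_n is usable at t_n + tau
    start: float | None = None  # first sample time; defaults to one period

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("measurement period must be positive")
        if self.delay < 0:
            raise ValueError("measurement delay must be >= 0")

    @classmethod
    def from_seconds(
        cls, period_s: float, delay_s: float = 0.0, start_s: float | None = None
    ) -> "MeasurementSchedule":
        return cls(
            period=period_s / SECONDS_PER_MINUTE,
            delay=delay_s / SECONDS_PER_MINUTE,
            start=None if start_s is None else start_s / SECONDS_PER_MINUTE,
        )

    def sample_times(self, t_end: float) -> np.ndarray:
        """Sample times in (0, t_end]."""
        start = self.period if self.start is None else self.start
        if start > t_end:
            return np.array([])
        n = int(np.floor((t_end - start) / self.period + 1e-9)) + 1
        return start + self.period * np.arange(n)


@dataclass(frozen=True)
class Measurement:
    """One sensor reading: taken at ``sample_time``, usable from
    ``available_time`` = sample_time + delay."""

    sample_time: float  # min
    available_time: float  # min
    value: float  # mg/L; may be negative (raw reading)
    is_failure: bool = False


@dataclass(frozen=True)
class FailureModel:
    """Out-of-distribution sensor failures.

    Each sample independently fails with ``probability``; a failed sample's
    value is replaced according to ``mode``:

    * ``"spike"``  — true value multiplied by a factor drawn uniformly from
      ``spike_range``;
    * ``"dropout"`` — reading of 0;
    * ``"stuck"``  — the previous reported value (or 0 for the first sample).
    """

    probability: float = 0.0
    mode: str = "spike"
    spike_range: tuple[float, float] = (3.0, 10.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("failure probability must be in [0, 1]")
        if self.mode not in ("spike", "dropout", "stuck"):
            raise ValueError("failure mode must be spike, dropout or stuck")


def sample_measurements(
    traj: CompartmentTrajectory,
    params: PKParameters,
    pop: PopulationModel,
    sched: MeasurementSchedule,
    rng: np.random.Generator,
    fail: FailureModel | None = None,
) -> list[Measurement]:
    """Generate the sensor's measurement stream for one subject.

    The true plasma concentration C1 = A1/V1 is linearly interpolated from the
    trajectory at each scheduled sample time, corrupted with the combined
    residual-error model, and (rarely) replaced by a failure value.  The
    returned list is ordered by availability time.
    """
    fail = fail or FailureModel()
    t_end = float(traj.times[-1])
    times = sched.sample_times(t_end)
    times = times[times >= traj.times[0]]
    if times.size == 0:
        raise ValueError("measurement schedule does not overlap the trajectory")
    c1_true = np.interp(times, traj.times, traj.A1 / params.V1)
    values = apply_residual_error(c1_true, pop, rng)
    failures = (
        rng.random(times.size) < fail.probability
        if fail.probability > 0
        else np.zeros(times.size, dtype=bool)
    )
    out: list[Measurement] = []
    prev_value = 0.0
    for t, c_true, y, failed in zip(times, c1_true, values, failures):
        if failed:
            if fail.mode == "spike":
                y = c_true * rng.uniform(*fail.spike_range)
            elif fail.mode == "dropout":
                y = 0.0
            else:  # stuck
                y = prev_value
        out.append(
            Measurement(
                sample_time=float(t),
                available_time=float(t + sched.delay),
                value=float(y),
                is_failure=bool(failed),
            )
        )
        prev_value = float(y)
    return out


def measurements_to_frame(measurements: list[Measurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_time_s": [m.sample_time * SECONDS_PER_MINUTE for m in measurements],
            "available_time_s": [
                m.available_time * SECONDS_PER_MINUTE for m in measurements
            ],
            "value_mg_per_L": [m.value for m in measurements],
            "is_failure": [m.is_failure for m in measurements],
        }
    )
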