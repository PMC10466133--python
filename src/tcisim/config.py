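"""YAML trial configuration: schema, validation, unit normalization.

Internally everything runs in minutes/mg/L; the config surface accepts
durations either as bare numbers (minutes) or as strings with an explicit
unit, e.g. ``"30 s"``, ``"0.5 min"``, ``"1 h"`` — sensor timing is most
naturally written in seconds.  Unknown keys are rejected so typos fail loudly
instead of silently running a different scenario.
"""

from __future__ import annotations

import re
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .actuator import ActuatorConfig
from .pk import PKParameters
from .population import Demographics, PopulationModel
from .sensor import FailureModel, MeasurementSchedule
from .trial import ARMS, TrialConfig

__all__ = ["load_config", "save_config", "config_to_dict", "parse_duration"]

_UNIT_TO_MIN = {"s": 1.0 / 60.0, "sec": 1.0 / 60.0, "min": 1.0, "h": 60.0, "hr": 60.0}
_DURATION_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*([a-zA-Z]+)\s*$")


def parse_duration(value) -> float:
    """Normalize a duration to minutes. Bare numbers are minutes; strings
    carry an explicit unit: '30 s', '0.5 min', '1 h'."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _DURATION_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse duration {value!r}")
    number, unit = m.groups()
    if unit not in _UNIT_TO_MIN:
        raise ValueError(f"unknown time unit {unit!r} in {value!r}")
    return float(number) * _UNIT_TO_MIN[unit]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class _PopulationSection(_Strict):
    means: dict[str, float]
    omegas: dict[str, float] = Field(default_factory=dict)
    prop: float = 0.0
    add: float = 0.0


class _SensorSection(_Strict):
    period: float | str
    delay: float | str = 0.0
    start: float | str | None = None

    @field_validator("period", "delay", "start")
    @classmethod
    def _parse(cls, v):
        return None if v is None else parse_duration(v)


class _FailureSection(_Strict):
    probability: float = 0.0
    mode: Literal["spike", "dropout", "stuck"] = "spike"
    spike_range: tuple[float, float] = (3.0, 10.0)


class _ActuatorSection(_Strict):
    max_rate_mg_per_min: float
    min_rate_step_mg_per_min: float = 0.0
    syringe_volume_mg: float = float("inf")
    low_reservoir_fraction: float = 0.1


class _DemographicsSection(_Strict):
    age_years: float = 36.0
    weight_kg: float = 70.0
    height_cm: float = 170.0
    sex: str = "female"


class _TrialSection(_Strict):
    n_subjects: int
    seed: int
    target_mg_per_L: float
    duration: float | str
    mode: Literal["plasma", "effect_site"] = "effect_site"
    control_interval: float | str | None = None
    horizon: float | str = 20.0
    arms: tuple[str, ...] = ARMS

    @field_validator("duration", "control_interval", "horizon")
    @classmethod
    def _parse(cls, v):
        return None if v is None else parse_duration(v)


class TrialConfigFile(_Strict):
    """Top-level schema of a trial YAML file."""

    population: _PopulationSection
    trial: _TrialSection
    sensor: _SensorSection
    actuator: _ActuatorSection
    failure: _FailureSection = Field(default_factory=_FailureSection)
    demographics: _DemographicsSection = Field(default_factory=_DemographicsSection)

    def build(self) -> TrialConfig:
        pop = PopulationModel(
            means=PKParameters.from_mapping(self.population.means),
            omegas=dict(self.population.omegas),
            prop=self.population.prop,
            add=self.population.add,
        )
        return TrialConfig(
            population=pop,
            n_subjects=self.trial.n_subjects,
            seed=self.trial.seed,
            target=self.trial.target_mg_per_L,
            duration=self.trial.duration,
            actuator=ActuatorConfig(
                max_rate=self.actuator.max_rate_mg_per_min,
                min_rate_step=self.actuator.min_rate_step_mg_per_min,
                syringe_volume=self.actuator.syringe_volume_mg,
                low_reservoir_fraction=self.actuator.low_reservoir_fraction,
            ),
            schedule=MeasurementSchedule(
                period=self.sensor.period,
                delay=self.sensor.delay,
                start=self.sensor.start,
            ),
            failure=FailureModel(
                probability=self.failure.probability,
                mode=self.failure.mode,
                spike_range=tuple(self.failure.spike_range),
            ),
            demographics=Demographics(
                age_years=self.demographics.age_years,
                weight_kg=self.demographics.weight_kg,
                height_cm=self.demographics.height_cm,
                sex=self.demographics.sex,
            ),
            mode=self.trial.mode,
            control_interval=self.trial.control_interval,
            horizon=self.trial.horizon,
            arms=tuple(self.trial.arms),
        )


def load_config(path) -> TrialConfig:
    """Load, validate and unit-normalize a trial YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    return TrialConfigFile.model_validate(raw).build()


def config_to_dict(cfg: TrialConfig) -> dict:
    """Serializable snapshot of a TrialConfig (all durations in minutes)."""
    from .pk import PARAM_NAMES

    return {
        "population": {
            "means": {n: getattr(cfg.population.means, n) for n in PARAM_NAMES},
            "omegas": dict(cfg.population.omegas),
            "prop": cfg.population.prop,
            "add": cfg.population.add,
        },
        "trial": {
            "n_subjects": cfg.n_subjects,
            "seed": cfg.seed,
            "target_mg_per_L": cfg.target,
            "duration": cfg.duration,
            "mode": cfg.mode,
            "control_interval": cfg.control_interval,
            "horizon": cfg.horizon,
            "arms": list(cfg.arms),
        },
        "sensor": {
            "period": cfg.schedule.period,
            "delay": cfg.schedule.delay,
            "start": cfg.schedule.start,
        },
        "actuator": {
            "max_rate_mg_per_min": cfg.actuator.max_rate,
            "min_rate_step_mg_per_min": cfg.actuator.min_rate_step,
            "syringe_volume_mg": cfg.actuator.syringe_volume,
            "low_reservoir_fraction": cfg.actuator.low_reservoir_fraction,
        },
        "failure": {
            "probability": cfg.failure.probability,
            "mode": cfg.failure.mode,
            "spike_range": list(cfg.failure.spike_range),
        },
        "demographics": {
            "age_years": cfg.demographics.age_years,
            "weight_kg": cfg.demographics.weight_kg,
            "height_cm": cfg.demographics.height_cm,
            "sex": cfg.demographics.sex,
        },
    }


def save_config(cfg: TrialConfig, path) -> None:
    data = config_to_dict(cfg)
    # YAML cannot represent inf portably; omit an unlimited syringe
    if data["actuator"]["syringe_volume_mg"] == float("inf"):
        del data["actuator"]["syringe_volume_mg"]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
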