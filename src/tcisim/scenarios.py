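"""Canonical built-in scenario.

The reference scenario is intravenous propofol delivery to a demographically
homogeneous adult cohort (36-year-old women, 70 kg, 170 cm): effect-site
target 6 mg/L, one plasma measurement every 30 s available 15 s later, and a
population model with published-scale between-subject variability on the
structural parameters (clearances and volumes) plus a combined
proportional+additive sensor error.

The structural constants and variances are transcribed literature values for
a reference adult under a broadly-applicable propofol PK model; they enter as
configuration, not as covariate equations.
"""

from __future__ import annotations

from .actuator import ActuatorConfig
from .pk import PKParameters
from .population import Demographics, PopulationModel
from .sensor import FailureModel, MeasurementSchedule
from .trial import TrialConfig

__all__ = ["propofol_reference_population", "reference_trial_config"]


def propofol_reference_population(
    prop: float = 0.2, add: float = 0.02
) -> PopulationModel:
    """Propofol population PK for the reference adult.

    Between-subject variability applies to clearances and volumes (the
    parameters the log-normal individual model perturbs); the effect-site
    constant ke0 is population-fixed.  omega values are log-scale SDs.
    """
    means = PKParameters(
        CL=2.10,  # L/min
        V1=6.28,  # L
        V2=25.5,  # L
        V3=273.0,  # L
        Q2=1.75,  # L/min
        Q3=1.11,  # L/min
        ke0=0.146,  # 1/min
    )
    omegas = {
        "CL": 0.515,
        "V1": 0.781,
        "V2": 0.752,
        "V3": 0.773,
        "Q2": 0.588,
        "Q3": 0.457,
    }
    return PopulationModel(means=means, omegas=omegas, prop=prop, add=add)


def reference_trial_config(
    n_subjects: int = 1000,
    seed: int = 20260101,
    duration: float = 15.0,
    target: float = 6.0,
    arms: tuple[str, ...] = ("open_loop", "closed_loop"),
) -> TrialConfig:
    """The canonical in-silico trial: effect-site target 6 mg/L, measurement
    period 30 s, delay 15 s, 1000 identical-demographics subjects."""
    return TrialConfig(
        population=propofol_reference_population(),
        n_subjects=n_subjects,
        seed=seed,
        target=target,
        duration=duration,
        actuator=ActuatorConfig(max_rate=200.0, syringe_volume=2000.0),
        schedule=MeasurementSchedule.from_seconds(period_s=30.0, delay_s=15.0),
        failure=FailureModel(probability=0.0),
        demographics=Demographics(),
        mode="effect_site",
        arms=arms,
    )
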