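"""Trial orchestration and cohort-level summary statistics.

A trial runs a virtual cohort through one or both study arms:

* **open-loop** — the classic TCI pump: a single rate schedule computed once
  from the population model is administered identically to every subject;
* **closed-loop** — the MAP-personalized controller adjusts each subject's
  rates from that subject's own noisy, delayed plasma measurements.

Cohort outcomes are summarized as the pointwise median concentration–time
profile with an empirical 95% prediction interval (2.5th/97.5th percentiles
across subjects), plus accuracy metrics around the target: the area of the
PI95 band over an equilibrated window, the fraction of subjects staying
within +/-10% of the target, and the worst relative deviation of any subject
from the population-model prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .actuator import ActuatorConfig
from .controller import ClosedLoopResult, run_closed_loop
from .pk import InfusionProfile, StatePropagator
from .population import Cohort, Demographics, PopulationModel, generate_cohort
from .sensor import FailureModel, MeasurementSchedule
from .tci import DEFAULT_HORIZON, TCIConfig, effect_site_targeting_rates, plasma_targeting_rates

__all__ = [
    "TrialConfig",
    "ArmResult",
    "CohortSummary",
    "run_trial",
    "summarize_ct_profiles",
    "accuracy_metrics",
]

ARMS = ("open_loop", "closed_loop")


@dataclass(frozen=True)
class TrialConfig:
    """Complete description of one in-silico trial."""

    population: PopulationModel
    n_subjects: int
    seed: int
    target: float  # mg/L
    duration: float  # min
    actuator: ActuatorConfig
    schedule: MeasurementSchedule
    failure: FailureModel = field(default_factory=FailureModel)
    demographics: Demographics = field(default_factory=Demographics)
    mode: str = "effect_site"
    control_interval: float | None = None  # min; defaults to the period
    horizon: float = DEFAULT_HORIZON
    arms: tuple[str, ...] = ARMS

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.target < 0 or self.duration <= 0:
            raise ValueError("target must be >= 0 and duration positive")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arms: {sorted(unknown)}")
        dt = self.control_interval
        if dt is not None and dt <= 0:
            raise ValueError("control_interval must be positive")

    @property
    def dt(self) -> float:
        return (
            self.control_interval
            if self.control_interval is not None
            else self.schedule.period
        )


@dataclass
class ArmResult:
    """Per-subject outcomes of one arm on a common time grid."""

    arm: str
    times: np.ndarray  # min
    C1: np.ndarray  # (n_subjects, n_times) mg/L
    C4: np.ndarray  # (n_subjects, n_times) mg/L
    profiles: list[InfusionProfile]
    subject_ids: list[str]
    events: list[dict] = field(default_factory=list)
    failed_subjects: dict[str, str] = field(default_factory=dict)

    def concentration(self, which: str) -> np.ndarray:
        if which not in ("C1", "C4"):
            raise ValueError("which must be 'C1' or 'C4'")
        return getattr(self, which)


@dataclass
class CohortSummary:
    """Pointwise median and 95% prediction interval across subjects."""

    times: np.ndarray
    median: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    which: str

    def __post_init__(self) -> None:
        if np.any(self.lo95 > self.median + 1e-12) or np.any(
            self.median > self.hi95 + 1e-12
        ):
            raise ValueError("percentile ordering violated")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                f"{self.which}_median": self.median,
                f"{self.which}_lo95": self.lo95,
                f"{self.which}_hi95": self.hi95,
            }
        )


def _common_grid(cfg: TrialConfig) -> np.ndarray:
    return np.round(np.arange(0.0, cfg.duration + 1e-9, cfg.dt), 9)


def _population_profile(cfg: TrialConfig):
    tci_cfg = TCIConfig(
        mode=cfg.mode,
        target=cfg.target,
        duration=cfg.duration,
        max_rate=cfg.actuator.max_rate,
        control_interval=cfg.dt,
        horizon=cfg.horizon,
    )
    fn = effect_site_targeting_rates if cfg.mode == "effect_site" else plasma_targeting_rates
    return fn(cfg.population.means, tci_cfg)


def population_reference(cfg: TrialConfig, which: str = "C4") -> np.ndarray:
    """Population-model predicted concentration on the trial grid — the curve
    an ideal average subject would follow under the open-loop schedule."""
    res = _population_profile(cfg)
    grid = _common_grid(cfg)
    pred = res.predicted_C4 if which == "C4" else res.predicted_C1
    return np.interp(grid, res.times, pred)


def _run_open_loop_arm(cfg: TrialConfig, cohort: Cohort, grid: np.ndarray) -> ArmResult:
    res = _population_profile(cfg)
    profile = res.profile
    sim_grid = np.unique(np.concatenate([grid, profile.times]))
    in_grid = np.isin(sim_grid, grid)
    n = len(cohort)
    C1 = np.empty((n, grid.size))
    C4 = np.empty((n, grid.size))
    ids, failed = [], {}
    for j, subj in enumerate(cohort):
        traj = StatePropagator(subj.params).run(profile, sim_grid)
        C1[j] = (traj.A1 / subj.params.V1)[in_grid]
        C4[j] = traj.C4[in_grid]
        ids.append(subj.subject_id)
    return ArmResult(
        arm="open_loop",
        times=grid,
        C1=C1,
        C4=C4,
        profiles=[profile] * n,
        subject_ids=ids,
        failed_subjects=failed,
    )


def _run_closed_loop_arm(cfg: TrialConfig, cohort: Cohort, grid: np.ndarray) -> ArmResult:
    n = len(cohort)
    C1 = np.full((n, grid.size), np.nan)
    C4 = np.full((n, grid.size), np.nan)
    profiles: list[InfusionProfile] = []
    ids, events, failed = [], [], {}
    # independent, order-invariant noise streams per subject
    children = np.random.SeedSequence((cfg.seed, 1)).spawn(n)
    for j, subj in enumerate(cohort):
        ids.append(subj.subject_id)
        rng = np.random.default_rng(children[j])
        try:
            res: ClosedLoopResult = run_closed_loop(
                subj,
                cfg.population,
                cfg.target,
                cfg.schedule,
                cfg.actuator,
                cfg.duration,
                rng,
                fail=cfg.failure,
                control_interval=cfg.dt,
                mode=cfg.mode,
            )
        except Exception as exc:  # keep the trial going, flag the subject
            failed[subj.subject_id] = str(exc)
            profiles.append(InfusionProfile([0.0], [0.0]))
            continue
        tr = res.trajectory
        C1[j] = np.interp(grid, tr.times, tr.A1 / subj.params.V1)
        C4[j] = np.interp(grid, tr.times, tr.C4)
        profiles.append(res.profile)
        for ev in res.events:
            events.append({"subject_id": subj.subject_id, **ev})
    return ArmResult(
        arm="closed_loop",
        times=grid,
        C1=C1,
        C4=C4,
        profiles=profiles,
        subject_ids=ids,
        events=events,
        failed_subjects=failed,
    )


def run_trial(cfg: TrialConfig) -> dict[str, ArmResult]:
    """Run the configured arms on a freshly generated cohort.

    Fully reproducible from the config: the cohort comes from ``cfg.seed``
    and each subject's sensor-noise stream from an independent child seed.
    """
    cohort = generate_cohort(
        cfg.population, cfg.n_subjects, cfg.seed, cfg.demographics
    )
    grid = _common_grid(cfg)
    results: dict[str, ArmResult] = {}
    if "open_loop" in cfg.arms:
        results["open_loop"] = _run_open_loop_arm(cfg, cohort, grid)
    if "closed_loop" in cfg.arms:
        results["closed_loop"] = _run_closed_loop_arm(cfg, cohort, grid)
    return results


def summarize_ct_profiles(arm: ArmResult, which: str = "C4") -> CohortSummary:
    """Pointwise median and empirical 2.5/97.5 percentiles across subjects
    (linear-interpolation quantile convention)."""
    conc = arm.concentration(which)
    if conc.shape[0] < 1 or np.all(np.isnan(conc)):
        raise ValueError("arm holds no subjects to summarize")
    lo, med, hi = np.nanpercentile(conc, [2.5, 50.0, 97.5], axis=0)
    return CohortSummary(times=arm.times, median=med, lo95=lo, hi95=hi, which=which)


def accuracy_metrics(
    arm: ArmResult,
    target: float,
    window: tuple[float, float] | None = None,
    which: str = "C4",
    reference: np.ndarray | None = None,
) -> dict[str, float]:
    """Target-accuracy metrics over an equilibrated window.

    Returns
    -------
    dict with
        ``pi95_area`` : integral of (hi95 - lo95) over the window, mg/L*min
        ``within_10pct_fraction`` : fraction of subjects whose concentration
            stays within +/-10% of the target throughout the window
        ``max_relative_deviation`` : worst |C_j(t) - C_ref(t)|/C_ref(t) over
            subjects and window times, against the population-model
            prediction ``reference`` (per-time array on the arm grid); when
            ``reference`` is None the cross-subject median is used.
    """
    if window is None:
        window = (arm.times[-1] / 2.0, arm.times[-1])  # second half of the trial
    lo_t, hi_t = window
    mask = (arm.times >= lo_t - 1e-12) & (arm.times <= hi_t + 1e-12)
    if not np.any(mask):
        raise ValueError("window does not overlap the trial grid")
    summary = summarize_ct_profiles(arm, which)
    band = summary.hi95[mask] - summary.lo95[mask]
    area = float(np.trapezoid(band, arm.times[mask]))

    conc = arm.concentration(which)[:, mask]
    if target <= 0:
        raise ValueError("relative accuracy metrics need a positive target")
    within = np.all(np.abs(conc - target) <= 0.1 * target, axis=1)
    fraction = float(np.mean(within))

    ref = (
        np.median(arm.concentration(which), axis=0)[mask]
        if reference is None
        else np.asarray(reference)[mask]
    )
    safe_ref = np.where(ref > 0, ref, np.nan)
    max_dev = float(np.nanmax(np.abs(conc - safe_ref) / safe_ref))
    return {
        "pi95_area": area,
        "within_10pct_fraction": fraction,
        "max_relative_deviation": max_dev,
    }


def flag_dosing_outliers(
    arm: ArmResult,
    target: float,
    window: tuple[float, float] | None = None,
    which: str = "C4",
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Under-/over-dosing report: subjects whose mean equilibrated
    concentration deviates from the target by more than ``threshold``."""
    if window is None:
        window = (arm.times[-1] / 2.0, arm.times[-1])
    mask = (arm.times >= window[0] - 1e-12) & (arm.times <= window[1] + 1e-12)
    mean_conc = arm.concentration(which)[:, mask].mean(axis=1)
    rel = (mean_conc - target) / target
    df = pd.DataFrame(
        {
            "subject_id": arm.subject_ids,
            "mean_conc_mg_per_L": mean_conc,
            "relative_deviation": rel,
        }
    )
    df["flag"] = np.select(
        [rel < -threshold, rel > threshold], ["underdosed", "overdosed"], default=""
    )
    return df[df["flag"] != ""].reset_index(drop=True)
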