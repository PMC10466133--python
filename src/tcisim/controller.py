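"""Closed-loop personalized infusion control.

The controller closes the loop around the open-loop TCI pump: it keeps a
maximum-a-posteriori (MAP) estimate of the subject's individual random
effects eta and re-solves the same per-interval targeting law against the
personalized model PAR_k * exp(eta_hat_k) every control interval, in the
spirit of receding-horizon model-predictive control.

MAP estimation.  Given measurements Y_n (taken at t_n, usable from t_n + tau)
and the infusion history actually administered, the estimate minimizes

    sum_n (Y_n - C1(t_n; PAR*e^eta))^2 / (prop^2*C1^2 + add^2)
      + sum_k eta_k^2 / omega_k^2

i.e. the residual-error likelihood plus the log-normal population prior.
Parameters with omega_k = 0 are not estimated.  The optimizer is warm-started
from the previous estimate and bounded at |eta_k| <= 5*omega_k so a single
outlying measurement cannot throw the estimate out of the population support.

With no measurements (or omega = 0) the estimate stays at the prior mode
eta = 0 and the closed loop is exactly the open-loop pump.

Causality is structural: a measurement enters the estimator's buffer only
when the event loop reaches its availability time, never at its sample time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .actuator import ActuatorConfig, constrain_rate, deplete
from .pk import CompartmentTrajectory, InfusionProfile, PKParameters, StatePropagator
from .population import PopulationModel, VirtualSubject, apply_residual_error
from .sensor import FailureModel, Measurement, MeasurementSchedule
from .tci import DEFAULT_HORIZON, DiscreteTCILaw

__all__ = [
    "ControllerState",
    "MAPPersonalizedTCI",
    "bayesian_update",
    "mpc_rate",
    "run_closed_loop",
    "ClosedLoopResult",
]

log = logging.getLogger(__name__)

_WEIGHT_FLOOR = 1e-12  # lower bound on the residual variance, (mg/L)^2


@dataclass
class ControllerState:
    """Everything the controller knows at a point in time."""

    target: float  # mg/L
    eta_hat: dict[str, float] = field(default_factory=dict)
    buffer: list[Measurement] = field(default_factory=list)
    infusion_times: list[float] = field(default_factory=list)  # segment starts, min
    infusion_rates: list[float] = field(default_factory=list)  # mg/min
    horizon: float = DEFAULT_HORIZON  # min

    def record_rate(self, t: float, rate: float) -> None:
        if self.infusion_times and np.isclose(t, self.infusion_times[-1]):
            self.infusion_rates[-1] = rate
        else:
            self.infusion_times.append(t)
            self.infusion_rates.append(rate)


def _predict_plasma(
    params: PKParameters,
    seg_times: np.ndarray,
    seg_rates: np.ndarray,
    obs_times: np.ndarray,
) -> np.ndarray:
    """Model plasma concentration C1 at ``obs_times`` under the piecewise
    infusion history, by exact discrete propagation."""
    return StatePropagator(params).plasma_series(seg_times, seg_rates, obs_times)


def _eta_params(pop: PopulationModel, names, eta_vec) -> PKParameters:
    return pop.means.scaled(
        {n: float(np.exp(e)) for n, e in zip(names, eta_vec)}
    )


def bayesian_update(
    pop: PopulationModel,
    state: ControllerState,
    include_failures: bool = True,
    maxiter: int = 40,
) -> dict[str, float]:
    """MAP estimate of the subject's random effects from the buffered
    measurements and the infusion history administered so far.

    Returns the updated eta_hat; on optimizer failure the previous estimate
    is kept and a warning is logged.
    """
    names = pop.variable_names
    if not names:
        return {}
    prior = {n: 0.0 for n in names}
    meas = state.buffer
    if not include_failures:
        meas = [m for m in meas if not m.is_failure]
    if not meas or not state.infusion_times:
        return dict(state.eta_hat) if state.eta_hat else prior

    obs_times = np.array([m.sample_time for m in meas])
    y = np.array([m.value for m in meas])
    seg_times = np.asarray(state.infusion_times)
    seg_rates = np.asarray(state.infusion_rates)
    omegas = np.array([pop.omegas[n] for n in names])
    x0 = np.array([state.eta_hat.get(n, 0.0) for n in names])

    # segment on/off lags as seen from each observation: fixed across all
    # candidate parameter vectors, so the objective is a pure superposition
    seg_ends = np.append(seg_times[1:], np.inf)
    dt_on = np.maximum(obs_times[:, None] - seg_times[None, :], 0.0)
    dt_off = np.maximum(obs_times[:, None] - seg_ends[None, :], 0.0)
    active = seg_rates != 0.0
    dt_on, dt_off, act_rates = dt_on[:, active], dt_off[:, active], seg_rates[active]

    def objective(eta_vec: np.ndarray) -> float:
        params = _eta_params(pop, names, eta_vec)
        sp = StatePropagator(params)
        c1 = (
            sp.plasma_superposition(dt_on, dt_off, act_rates)
            if sp._eig_ok
            else sp.plasma_series(seg_times, seg_rates, obs_times)
        )
        w = np.maximum(pop.prop**2 * c1**2 + pop.add**2, _WEIGHT_FLOOR)
        return float(
            np.sum((y - c1) ** 2 / w) + np.sum(eta_vec**2 / omegas**2)
        )

    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(-5 * om, 5 * om) for om in omegas],
        options={"maxiter": maxiter},
    )
    if not np.all(np.isfinite(res.x)):  # pragma: no cover - defensive
        log.warning("MAP optimization diverged; keeping previous estimate")
        return dict(state.eta_hat) if state.eta_hat else prior
    if not res.success and res.status != 1:  # status 1 = maxiter, acceptable
        log.warning("MAP optimization did not converge: %s", res.message)
    return {n: float(v) for n, v in zip(names, res.x)}


def mpc_rate(
    pop: PopulationModel,
    state: ControllerState,
    act: ActuatorConfig,
    control_interval: float,
    mode: str = "effect_site",
    law: DiscreteTCILaw | None = None,
    now: float | None = None,
) -> float:
    """Next-interval delivery rate for the personalized model.

    Re-derives the personalized model state from the administered infusion
    history, then applies the same discrete targeting law as the open-loop
    pump; with eta_hat = 0 this is the open-loop TCI rate.
    """
    names = pop.variable_names
    eta_vec = np.array([state.eta_hat.get(n, 0.0) for n in names])
    params = _eta_params(pop, names, eta_vec)
    if law is None or law.params != params:
        law = DiscreteTCILaw(params, control_interval, state.horizon)
    x = _personalized_state(law.prop, state, now)
    u, _ = law.rate(mode, x, state.target, act.max_rate)
    return u


def _personalized_state(
    sp: StatePropagator, state: ControllerState, now: float | None = None
) -> np.ndarray:
    """Model state at time ``now`` implied by the infusion history under
    ``sp``'s parameters.  ``None`` means the end of the recorded history."""
    x = np.zeros(4)
    times = state.infusion_times
    rates = state.infusion_rates
    ends = list(times[1:]) + [now if now is not None else times[-1] if times else 0.0]
    for t0, t1, u in zip(times, ends, rates):
        if t1 > t0:
            x = sp.step(x, t1 - t0, u)
    return x


@dataclass
class ClosedLoopResult:
    """Outcome of one closed-loop run for one subject."""

    trajectory: CompartmentTrajectory  # true subject states on the event grid
    profile: InfusionProfile  # rates actually delivered
    measurements: list[Measurement]
    events: list[dict]  # time, event_type, payload columns
    eta_history: list[tuple[float, dict[str, float]]]


class MAPPersonalizedTCI:
    """The canonical closed-loop controller: MAP estimator + personalized
    per-interval targeting law.

    Both pieces are pluggable: subclasses (or instances with swapped
    callables) can replace ``estimate`` or ``compute_rate`` to realise other
    controller variants over the same trial infrastructure.
    """

    def __init__(
        self,
        pop: PopulationModel,
        target: float,
        act: ActuatorConfig,
        control_interval: float,
        mode: str = "effect_site",
        horizon: float = DEFAULT_HORIZON,
        include_failures: bool = True,
    ):
        self.pop = pop
        self.act = act
        self.control_interval = control_interval
        self.mode = mode
        self.include_failures = include_failures
        self.state = ControllerState(target=target, horizon=horizon)
        self.state.eta_hat = {n: 0.0 for n in pop.variable_names}
        self._law = DiscreteTCILaw(pop.means, control_interval, horizon)
        self._n_updates = 0

    def receive(self, m: Measurement) -> None:
        self.state.buffer.append(m)

    def estimate(self) -> None:
        # warm-started re-estimates need only a few quasi-Newton iterations
        maxiter = 40 if self._n_updates == 0 else 12
        self._n_updates += 1
        eta = bayesian_update(self.pop, self.state, self.include_failures, maxiter)
        if eta != self.state.eta_hat:
            self.state.eta_hat = eta
            names = self.pop.variable_names
            params = _eta_params(
                self.pop, names, [eta[n] for n in names]
            )
            self._law = DiscreteTCILaw(params, self.control_interval, self.state.horizon)

    def compute_rate(self, now: float | None = None) -> float:
        x = _personalized_state(self._law.prop, self.state, now)
        u, _ = self._law.rate(self.mode, x, self.state.target, self.act.max_rate)
        return u


def run_closed_loop(
    subject: VirtualSubject,
    pop: PopulationModel,
    target: float,
    sched: MeasurementSchedule,
    act: ActuatorConfig,
    duration: float,
    rng: np.random.Generator,
    fail: FailureModel | None = None,
    control_interval: float | None = None,
    mode: str = "effect_site",
    controller: MAPPersonalizedTCI | None = None,
) -> ClosedLoopResult:
    """Event-driven closed-loop run for one subject.

    The subject's true dynamics are advanced by exact piecewise-constant
    stepping with the subject's own parameters; the controller only ever sees
    noisy, delayed measurements of the true plasma concentration and the
    rates it has itself commanded.
    """
    fail = fail or FailureModel()
    dt = control_interval if control_interval is not None else sched.period
    controller = controller or MAPPersonalizedTCI(
        pop, target, act, dt, mode=mode
    )

    # round event times to avoid float-identity misses when periods are not
    # exactly representable (e.g. 20 s = 1/3 min)
    r = lambda a: np.round(np.asarray(a, dtype=float), 9)
    ticks = r(np.arange(0.0, duration + 1e-9, dt))
    sample_times = r(sched.sample_times(duration))
    avail_times = r(sample_times + sched.delay)
    event_times = np.unique(
        np.concatenate(
            [ticks, sample_times, avail_times[avail_times <= duration], r([duration])]
        )
    )
    is_tick = np.isin(event_times, ticks)
    is_sample = np.isin(event_times, sample_times)
    is_avail = np.isin(event_times, avail_times)

    sp_true = StatePropagator(subject.params)
    x = np.zeros(4)
    reservoir = act.syringe_volume
    pending: list[Measurement] = []
    measurements: list[Measurement] = []
    events: list[dict] = []
    eta_history: list[tuple[float, dict[str, float]]] = []
    states = np.zeros((event_times.size, 4))
    prev_stuck = 0.0
    prev_flags: set[str] = set()
    rate = 0.0

    for i, t in enumerate(event_times):
        if i > 0:
            step = event_times[i] - event_times[i - 1]
            # truncate delivery to what the reservoir can still supply
            reservoir, delivered = deplete(reservoir, rate, step)
            effective = delivered / step if step > 0 else 0.0
            x = sp_true.step(x, step, effective)
        states[i] = x

        if is_sample[i]:
            c_true = x[0] / subject.params.V1
            y = apply_residual_error(float(c_true), pop, rng)
            failed = bool(rng.random() < fail.probability)
            if failed:
                if fail.mode == "spike":
                    y = float(c_true * rng.uniform(*fail.spike_range))
                elif fail.mode == "dropout":
                    y = 0.0
                else:
                    y = prev_stuck
            m = Measurement(float(t), float(t + sched.delay), float(y), failed)
            prev_stuck = m.value
            pending.append(m)
            measurements.append(m)
            events.append({"time": t, "event_type": "measure", "value": m.value})

        new_info = False
        if is_avail[i] and pending:
            while pending and pending[0].available_time <= t + 1e-6:
                controller.receive(pending.pop(0))
                new_info = True
            if new_info:
                controller.estimate()
                eta_history.append((float(t), dict(controller.state.eta_hat)))
                events.append(
                    {
                        "time": t,
                        "event_type": "update",
                        "value": float(
                            np.linalg.norm(
                                list(controller.state.eta_hat.values()) or [0.0]
                            )
                        ),
                    }
                )

        # the pump is only re-commanded on control ticks; estimator updates
        # arriving between ticks take effect at the next tick
        if is_tick[i] and t < duration:
            requested = controller.compute_rate(float(t))
            actual, flags = constrain_rate(requested, act, reservoir)
            for flag in flags - prev_flags:
                events.append({"time": t, "event_type": "alarm", "value": flag})
            prev_flags = flags
            if actual != rate:
                events.append({"time": t, "event_type": "rate_change", "value": actual})
            rate = actual
            controller.state.record_rate(float(t), rate)

    traj = CompartmentTrajectory(
        times=event_times,
        A1=states[:, 0],
        A2=states[:, 1],
        A3=states[:, 2],
        C4=states[:, 3],
    )
    seg_t = np.asarray(controller.state.infusion_times)
    seg_r = np.asarray(controller.state.infusion_rates)
    if seg_t.size == 0:
        seg_t, seg_r = np.array([0.0]), np.array([0.0])
    keep = np.concatenate([[True], np.diff(seg_r) != 0])
    profile = InfusionProfile(seg_t[keep], seg_r[keep], duration=float(duration))
    return ClosedLoopResult(traj, profile, measurements, events, eta_history)
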