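# Methods

This note records the modeling assumptions, default parameter values,
numerical methods, and design decisions behind `tcisim`, and what the
generator does and does not claim to emulate.

## 1. Model

### 1.1 Pharmacokinetics

Drug disposition is a linear three-compartment mammillary model.  States are
amounts `A1, A2, A3` (mg) in the central (plasma), fast-peripheral and
slow-peripheral compartments; the input `U(t)` (mg/min) is a piecewise
constant infusion into the central compartment:

    dA1/dt = A2*k21 + A3*k31 − A1*(k10 + k12 + k13) + U(t)
    dA2/dt = A1*k12 − A2*k21
    dA3/dt = A1*k13 − A3*k31

Micro rate constants derive from clearances and volumes by the mammillary
convention `k10 = CL/V1`, `k12 = Q2/V1`, `k21 = Q2/V2`, `k13 = Q3/V1`,
`k31 = Q3/V3` (all 1/min).

A fourth, *massless* effect-site compartment tracks the delayed drug effect.
Its concentration obeys

    dC4/dt = (C1 − C4) * ke0,      C1 = A1/V1

The associated micro-constants are `k41 = ke0` (out of the effect site) and
`k14 = ke0 / 10000` (into it).  The fixed ratio 10000 encodes the modeling
assumption that the effect site holds negligible mass: `k14` is reported by
the rate-constant derivation but, because the compartment is treated as
massless, no `k14` term is needed in the plasma balance — the approximation
the 1:10000 ratio is designed to justify.

Units throughout the package: minutes, mg, L, mg/L.

### 1.2 Between-subject variability

Each subject `j` perturbs every population parameter `PAR_k` log-normally,

    PAR_kj = PAR_k * exp(eta_kj),     eta_kj ~ N(0, omega_k^2)

applied to `CL, V1, V2, V3, Q2, Q3` (and optionally `ke0`; the reference
scenario keeps `ke0` fixed).  Log-normal sampling guarantees positivity and
makes the population value the subject-median.

### 1.3 Residual (measurement) error

A sensor reading of a true concentration `C` is

    Y = C + sqrt(prop^2 * C^2 + add^2) * eps,    eps ~ N(0, 1)

i.e. a combined proportional + additive error model with standard deviation
`sqrt(prop^2 C^2 + add^2)`.  The additive floor keeps the noise
non-degenerate at `C = 0` and the proportional term reproduces the
concentration-proportional spread typical of bioanalytical assays.

### 1.4 Sensor, actuator, failures

Measurements are taken every `period` minutes and become usable to the
controller only `delay` minutes later; causality is structural in the event
loop (a value enters the estimator's buffer at its availability time, never
at its sample time).  Optional failure modes replace a reading with a
positive-bias spike (3–10× truth), a dropout (0), or the previous value
("stuck"), each with a configurable probability.

The pump saturates at `max_rate`, optionally quantizes rates to
`min_rate_step`, draws from a finite syringe reservoir, and raises
low-reservoir/empty/saturation alarms.  When the reservoir runs out
mid-interval the delivered rate is truncated to what remained.

### 1.5 Controllers

*Open-loop TCI.*  A discrete-time targeting law with interval `dt` computes,
at each tick, the largest rate that does not push the predicted
concentration above the setpoint anywhere on a look-ahead horizon:
`U* = clip(min_m (target − free_m)/resp_m, 0, max_rate)`, where `free_m` is
the zero-input prediction at horizon step `m` and `resp_m` the unit-rate
response.  For plasma targeting only the next step matters (the law reduces
to exact one-step deadbeat); for effect-site targeting the minimum over the
horizon produces the classic profile — a maximal bolus, a pause while the
effect site coasts up to its peak exactly at the target, then maintenance.

*Closed loop.*  The same targeting law re-solved every control interval
against a personalized model `PAR_k * exp(eta_hat_k)`, in the spirit of
receding-horizon model-predictive control.  `eta_hat` is the MAP estimate
minimizing

    sum_n (Y_n − C1(t_n; PAR e^eta))^2 / (prop^2 C1^2 + add^2)
        + sum_k eta_k^2 / omega_k^2

over all measurements received so far and the infusion history the
controller itself administered (L-BFGS-B, warm-started, bounded at
`|eta_k| <= 5 omega_k`).  With no measurements, or `omega = 0`, the estimate
stays at the prior mode and the closed loop reproduces the open-loop pump
exactly — the two arms differ only through information, by construction.

## 2. Reference scenario and defaults

The shipped scenario (`examples/propofol_trial.yaml`,
`tcisim.scenarios.reference_trial_config`) models IV propofol in a reference
adult (36 y, 70 kg, 170 cm, female):

| parameter | value | units |
|---|---|---|
| CL | 2.10 | L/min |
| V1 | 6.28 | L |
| V2 | 25.5 | L |
| V3 | 273 | L |
| Q2 | 1.75 | L/min |
| Q3 | 1.11 | L/min |
| ke0 | 0.146 | 1/min |
| omega (CL, V1, V2, V3, Q2, Q3) | 0.515, 0.781, 0.752, 0.773, 0.588, 0.457 | — |
| prop, add | 0.20, 0.02 | —, mg/L |

These are transcriptions of a published adult propofol population model and
its variances; they are configuration data, not package logic — any valid
parameter set runs identically.  Trial defaults: 1000 subjects, effect-site
target 6 mg/L, 15 min duration, measurement period 30 s, reporting delay
15 s, control interval = measurement period, pump limit 200 mg/min, 2000 mg
syringe.

## 3. Numerical methods

Two independent routes compute the same dynamics and are cross-checked in
the test suite:

1. **ODE integration** (`tcisim.pk.simulate`): LSODA via
   `scipy.integrate.solve_ivp`, restarted at each rate breakpoint so the
   discontinuous input never crosses a solver step; `rtol = 1e-8`,
   `atol = 1e-10`.  A fifth quadrature state accumulates eliminated drug
   `∫ A1 k10 dt` so mass balance (infused = retained + eliminated) is audited
   at solver accuracy on every simulation.
2. **Exact discrete propagation** (`tcisim.pk.StatePropagator`): the
   piecewise-constant system is advanced by the matrix exponential.  The 3×3
   mammillary block is symmetrized by the similarity transform
   `D = diag(sqrt(V_i))` and diagonalized with `numpy.linalg.eigh`; the
   effect-site eigenpair follows in closed form.  This makes per-step
   propagation exact to machine precision and fast enough for the MAP
   estimator's inner loop, where plasma predictions are evaluated by
   superposition of segment step-responses, vectorized across measurement
   times and infusion segments.  A third, structure-free oracle (Van Loan
   augmented-matrix exponential via `scipy.linalg.expm`) validates both.

Other conventions:

- Cohort generation draws one child of `numpy.random.SeedSequence(seed)` per
  subject, so results are independent of iteration order and bit-identical
  across runs and platforms; closed-loop sensor noise uses a separate child
  stream per subject.
- Cohort summaries are pointwise medians and empirical 2.5/97.5 percentiles
  (NumPy's linear-interpolation quantile convention).  Accuracy metrics
  (PI95 band area, within-±10% fraction, maximum relative deviation) are
  evaluated over the second half of the trial unless a window is given, so
  induction transients do not dominate.
- Event times in the closed loop are rounded to 9 decimals before merging so
  non-dyadic periods (e.g. 20 s = 1/3 min) cannot miss coincident events.
- CSV round-trips use `%.17g` formatting and round-trip float parsing, so
  exported cohorts and profiles reload bit-identically.

## 4. What the generator emulates — and what it does not

Emulated: between-subject PK variability, assay-like measurement noise,
sampling period and reporting latency, sensor failure modes, pump saturation
and reservoir limits, and the information asymmetry between an open-loop and
a feedback device.

Not emulated: pharmacodynamics beyond the effect-site concentration (no
BIS/effect model, no clinical endpoints), intra-subject parameter drift or
time-varying physiology, drug interactions, covariate models (demographics
are recorded metadata, not covariates of the PK parameters), actuator
dynamics beyond rate limits (no tubing dead volume or compliance), and any
hardware or human-factors failure of the device itself.

## 5. Design decisions

- One canonical closed-loop controller (MAP + personalized targeting law) is
  shipped; its estimator and rate law are pluggable hooks for variants.
- The open-loop and closed-loop arms share one targeting-law implementation,
  so arm comparisons isolate the value of feedback rather than algorithmic
  differences.
- The pump is re-commanded only on control ticks; estimator updates arriving
  between ticks take effect at the next tick, as a fixed-interval infusion
  pump would.
- Problem sizes in the test and acceptance suites (cohort sizes, replicate
  counts, durations) are the package's own choices, balancing statistical
  resolution against single-CPU runtime.

## 6. Limitations

Conclusions transfer to real devices only as far as the PK model and noise
model hold.  The MAP estimator shares the structural model with the virtual
patients (no model mismatch beyond the sampled parameters), which flatters
the closed loop relative to reality.  Identifiability limits apply: with few
measurements, only a low-dimensional `eta` (e.g. clearance and central
volume) is practically recoverable, and the estimator's prior bounds
(`±5 omega`) assume the population model is roughly right.  Residual error is
assumed Gaussian and uncorrelated across samples.
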