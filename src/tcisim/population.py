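"""Population PK model: between-subject variability and residual error.

A virtual subject j is drawn from the population by perturbing each structural
parameter log-normally,

    PAR_k^j = PAR_k * exp(eta_k^j),     eta_k^j ~ N(0, omega_k^2) independent,

so PAR_k is the population geometric mean and omega_k the between-subject
standard deviation on the log scale.  A parameter with omega_k = 0 is fixed at
its population value.

Sensor-level (within-subject) noise follows the standard combined residual
model

    Y = C + sqrt(prop^2 * C^2 + add^2) * eps,   eps ~ N(0, 1),

reducing to a purely proportional model when add = 0 and a purely additive one
when prop = 0.  Raw readings may be negative; clipping is left to consumers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pk import PARAM_NAMES, PKParameters

__all__ = [
    "Demographics",
    "PopulationModel",
    "VirtualSubject",
    "Cohort",
    "sample_subject",
    "generate_cohort",
    "apply_residual_error",
]


@dataclass(frozen=True)
class Demographics:
    """Subject demographics. Metadata only: the cohorts simulated here are
    demographically homogeneous and parameters arrive via the population
    model, not via covariate equations."""

    age_years: float = 36.0
    weight_kg: float = 70.0
    height_cm: float = 170.0
    sex: str = "female"


@dataclass(frozen=True)
class PopulationModel:
    """Population means, between-subject SDs and residual-error terms.

    means : population (geometric-mean) PK parameters
    omegas : per-parameter log-scale SD omega_k; parameters absent from the
        mapping carry omega = 0 and are fixed at their population value
    prop : proportional residual term (dimensionless)
    add : additive residual term (mg/L)
    """

    means: PKParameters
    omegas: dict[str, float] = field(default_factory=dict)
    prop: float = 0.0
    add: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.omegas) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"omegas refer to unknown parameters: {sorted(unknown)}")
        for name, om in self.omegas.items():
            if om < 0 or not np.isfinite(om):
                raise ValueError(f"omega for {name} must be finite and >= 0")
        if self.prop < 0 or self.add < 0:
            raise ValueError("residual terms prop and add must be >= 0")

    def omega_vector(self) -> np.ndarray:
        return np.array([self.omegas.get(n, 0.0) for n in PARAM_NAMES])

    @property
    def variable_names(self) -> tuple[str, ...]:
        """Parameters with omega > 0 (the ones a subject can differ in)."""
        return tuple(n for n in PARAM_NAMES if self.omegas.get(n, 0.0) > 0)

    def residual_sd(self, C) -> np.ndarray:
        """SD of the combined residual error at true concentration(s) C."""
        C = np.asarray(C, dtype=float)
        return np.sqrt(self.prop**2 * C**2 + self.add**2)


@dataclass(frozen=True)
class VirtualSubject:
    """One virtual patient: identity, demographics, random effects, and the
    individual parameters PAR_k = mean_k * exp(eta_k)."""

    subject_id: str
    demographics: Demographics
    etas: dict[str, float]
    params: PKParameters


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[VirtualSubject, ...]
    seed: int
    population: PopulationModel

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "age_years": s.demographics.age_years,
                "weight_kg": s.demographics.weight_kg,
                "height_cm": s.demographics.height_cm,
                "sex": s.demographics.sex,
            }
            row.update({n: getattr(s.params, n) for n in PARAM_NAMES})
            row.update({f"eta_{n}": s.etas.get(n, 0.0) for n in PARAM_NAMES})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        # %.17g keeps float64 round-trippable through the CSV
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, population: PopulationModel, seed: int = 0) -> "Cohort":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(df, population, seed)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, population: PopulationModel, seed: int = 0
    ) -> "Cohort":
        subjects = []
        for _, row in df.iterrows():
            subjects.append(
                VirtualSubject(
                    subject_id=str(row["subject_id"]),
                    demographics=Demographics(
                        age_years=float(row["age_years"]),
                        weight_kg=float(row["weight_kg"]),
                        height_cm=float(row["height_cm"]),
                        sex=str(row["sex"]),
                    ),
                    etas={n: float(row[f"eta_{n}"]) for n in PARAM_NAMES},
                    params=PKParameters.from_mapping(row),
                )
            )
        return cls(tuple(subjects), seed, population)


def sample_subject(
    pop: PopulationModel,
    rng: np.random.Generator,
    demographics: Demographics | None = None,
    subject_id: str = "S0001",
) -> VirtualSubject:
    """Draw one subject: independent eta_k ~ N(0, omega_k^2) per parameter.

    Parameters with omega = 0 consume no random numbers, so adding a fixed
    parameter does not shift the draws of the others.
    """
    demographics = demographics or Demographics()
    etas: dict[str, float] = {}
    factors: dict[str, float] = {}
    for name in PARAM_NAMES:
        omega = pop.omegas.get(name, 0.0)
        eta = float(rng.normal(0.0, omega)) if omega > 0 else 0.0
        etas[name] = eta
        factors[name] = float(np.exp(eta))
    return VirtualSubject(
        subject_id=subject_id,
        demographics=demographics,
        etas=etas,
        params=pop.means.scaled(factors),
    )


def generate_cohort(
    pop: PopulationModel,
    n: int,
    seed: int,
    demographics: Demographics | None = None,
) -> Cohort:
    """Generate a reproducible virtual cohort of ``n`` subjects.

    Each subject gets an independent child stream spawned from ``seed``
    (one :class:`numpy.random.SeedSequence` per subject), so the cohort is
    bit-identical across runs and invariant to evaluation order.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    demographics = demographics or Demographics()
    width = max(4, len(str(n)))
    children = np.random.SeedSequence(seed).spawn(n)
    subjects = tuple(
        sample_subject(
            pop,
            np.random.default_rng(children[j]),
            demographics,
            subject_id=f"S{j + 1:0{width}d}",
        )
        for j in range(n)
    )
    return Cohort(subjects=subjects, seed=seed, population=pop)


def apply_residual_error(
    C, pop: PopulationModel, rng: np.random.Generator
) -> np.ndarray | float:
    """Corrupt true concentration(s) with combined proportional+additive noise.

    Returns Y = C + sqrt(prop^2 C^2 + add^2) * eps with eps ~ N(0,1) drawn per
    element.  Y may be negative for small C; that is the raw sensor reading.
    """
    C_arr = np.asarray(C, dtype=float)
    if np.any(C_arr < 0):
        raise ValueError("true concentration must be non-negative")
    eps = rng.standard_normal(C_arr.shape)
    Y = C_arr + pop.residual_sd(C_arr) * eps
    return float(Y) if np.ndim(C) == 0 else Y
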