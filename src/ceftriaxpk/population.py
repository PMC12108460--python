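"""Covariate and random-effects layer of the population PK model.

Individual parameters follow the usual log-normal mixed-effects form.  For
a parameter p with population value theta_pop and covariate effects
(cov, beta, ref)::

    theta_i = theta_pop * prod (cov_i / ref)**beta  * exp(eta_i)      (continuous)
    theta_i = theta_pop * beta**indicator * exp(eta_i)                 (categorical)

with eta_i ~ Normal(0, omega_p**2) on the log scale, independent across
parameters (diagonal omega).  The residual model is additive Gaussian with
standard deviation sigma (mg/L), matching a constant-error model for the
free-concentration observations.

The published final model has CrCl on CL (exponent 0.62, reference median
59.5 mL/min/1.73 m2) and BMI on V1 (exponent 2.52, reference 29.3 kg/m2).
:func:`final_model` returns that model with its reported variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structural import StructuralParams

__all__ = [
    "PARAM_NAMES",
    "Covariates",
    "CovariateEffect",
    "PopulationModel",
    "final_model",
    "individual_params",
    "sample_etas",
    "add_residual",
]

PARAM_NAMES: tuple[str, ...] = ("CL", "V1", "Q", "V2")

#: covariates treated as 0/1 indicators in covariate effects
CATEGORICAL_COVARIATES = frozenset({"sex"})


@dataclass(frozen=True)
class Covariates:
    """Subject-level covariates.

    crcl
        Creatinine clearance standardised to 1.73 m2 body surface area,
        mL/min/1.73 m2.
    bmi
        Body mass index, kg/m2.
    age
        Years.
    weight
        Kg.
    sex
        0 = female, 1 = male.
    """

    crcl: float
    bmi: float
    age: float
    weight: float
    sex: int

    def __post_init__(self) -> None:
        for name in ("crcl", "bmi", "age", "weight"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 or 1, got {self.sex}")

    def value(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate effect on one structural parameter.

    For a continuous covariate, ``beta`` is the power-model exponent and
    ``reference`` the normalising median.  For a categorical covariate
    (``sex``), ``beta`` is the multiplicative factor applied when the
    indicator equals 1 and ``reference`` is ignored.
    """

    parameter: str
    covariate: str
    beta: float
    reference: float = 1.0

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if not self.is_categorical and not self.reference > 0:
            raise ValueError("reference median must be > 0")

    @property
    def is_categorical(self) -> bool:
        return self.covariate in CATEGORICAL_COVARIATES

    def factor(self, cov: Covariates) -> float:
        x = cov.value(self.covariate)
        if self.is_categorical:
            return float(self.beta) if x == 1 else 1.0
        if x <= 0:
            raise ValueError(
                f"covariate {self.covariate!r} must be > 0 where a power "
                f"effect applies, got {x}"
            )
        return float((x / self.reference) ** self.beta)


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, covariate effects and variability of the population model.

    theta_pop
        Population values of (CL, V1, Q, V2) in L/h, L, L/h, L.
    covariate_effects
        Multiplicative covariate effects (see :class:`CovariateEffect`).
    omega
        Between-subject SD per parameter on the log scale, same order as
        :data:`PARAM_NAMES`. Entries >= 0.
    sigma
        Additive residual SD, mg/L. > 0.
    """

    theta_pop: dict[str, float]
    covariate_effects: tuple[CovariateEffect, ...] = ()
    omega: dict[str, float] = field(
        default_factory=lambda: {p: 0.0 for p in PARAM_NAMES}
    )
    sigma: float = 1.0

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.theta_pop)
        if missing:
            raise ValueError(f"theta_pop missing {sorted(missing)}")
        for p in PARAM_NAMES:
            if p != "Q" and not self.theta_pop[p] > 0:
                raise ValueError(f"theta_pop[{p!r}] must be > 0")
            if self.theta_pop["Q"] < 0:
                raise ValueError("theta_pop['Q'] must be >= 0")
            if self.omega.get(p, 0.0) < 0:
                raise ValueError(f"omega[{p!r}] must be >= 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))

    def omega_vector(self) -> np.ndarray:
        return np.array([self.omega.get(p, 0.0) for p in PARAM_NAMES])

    def with_effect(self, effect: CovariateEffect) -> "PopulationModel":
        return replace(self, covariate_effects=self.covariate_effects + (effect,))


def final_model() -> PopulationModel:
    """The published final free-ceftriaxone model for elderly IE patients.

    CL 11.57 L/h, V1 43.6 L, Q 19.8 L/h, V2 40.94 L; CrCl on CL with
    exponent 0.62 (reference 59.5 mL/min/1.73 m2), BMI on V1 with exponent
    2.52 (reference 29.3 kg/m2); omega = (0.48, 0.77, 0.75, 0.09); additive
    sigma = 1.41 mg/L.
    """
    return PopulationModel(
        theta_pop={"CL": 11.57, "V1": 43.6, "Q": 19.8, "V2": 40.94},
        covariate_effects=(
            CovariateEffect("CL", "crcl", 0.62, 59.5),
            CovariateEffect("V1", "bmi", 2.52, 29.3),
        ),
        omega={"CL": 0.48, "V1": 0.77, "Q": 0.75, "V2": 0.09},
        sigma=1.41,
    )


def individual_params(
    pop: PopulationModel, cov: Covariates, eta: np.ndarray | dict[str, float]
) -> StructuralParams:
    """Map population model + covariates + eta deviates to individual parameters.

    ``eta`` is either a length-4 array in :data:`PARAM_NAMES` order or a
    mapping; missing parameters default to 0.
    """
    if isinstance(eta, dict):
        eta_vec = np.array([eta.get(p, 0.0) for p in PARAM_NAMES])
    else:
        eta_vec = np.asarray(eta, dtype=float)
        if eta_vec.shape != (len(PARAM_NAMES),):
            raise ValueError(f"eta must have shape (4,), got {eta_vec.shape}")
    if not np.all(np.isfinite(eta_vec)):
        raise ValueError("eta must be finite")
    values = {}
    for i, p in enumerate(PARAM_NAMES):
        v = pop.theta_pop[p]
        for eff in pop.covariate_effects:
            if eff.parameter == p:
                v *= eff.factor(cov)
        values[p] = v * float(np.exp(eta_vec[i]))
    return StructuralParams(**values)


def individual_param_matrix(
    pop: PopulationModel, cov_table, etas: np.ndarray
) -> np.ndarray:
    """Vectorised :func:`individual_params` for a whole population.

    ``cov_table`` is a mapping or DataFrame with columns/keys
    ``crcl, bmi, age, weight, sex`` holding length-n arrays; ``etas`` is
    ``(n, 4)``.  Returns an ``(n, 4)`` array in :data:`PARAM_NAMES` order.
    """
    etas = np.asarray(etas, dtype=float)
    n = etas.shape[0]
    out = np.empty((n, len(PARAM_NAMES)))
    for i, p in enumerate(PARAM_NAMES):
        v = np.full(n, pop.theta_pop[p])
        for eff in pop.covariate_effects:
            if eff.parameter != p:
                continue
            x = np.asarray(cov_table[eff.covariate], dtype=float)
            if eff.is_categorical:
                v = v * np.where(x == 1, eff.beta, 1.0)
            else:
                if np.any(x <= 0):
                    raise ValueError(
                        f"covariate {eff.covariate!r} must be > 0 where a "
                        "power effect applies"
                    )
                v = v * (x / eff.reference) ** eff.beta
        out[:, i] = v * np.exp(etas[:, i])
    return out


def sample_etas(
    pop: PopulationModel, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw an ``n x 4`` matrix of between-subject deviates.

    Columns are independent Normal(0, omega_p) on the log scale, in
    :data:`PARAM_NAMES` order; a column with omega_p = 0 is identically zero.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    return rng.standard_normal((n, len(PARAM_NAMES))) * pop.omega_vector()


def add_residual(
    conc: np.ndarray, sigma: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Add additive Gaussian residual error to a concentration series."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    conc = np.asarray(conc, dtype=float)
    if sigma == 0:
        return conc.copy()
    rng = np.random.default_rng(rng)
    return conc + rng.normal(0.0, sigma, size=conc.shape)
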