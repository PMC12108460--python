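"""Closed-form two-compartment disposition with zero-order (infusion) input.

The structural model is the standard mammillary two-compartment system
parameterised by clearance ``CL``, central volume ``V1``, intercompartmental
clearance ``Q`` and peripheral volume ``V2``.  Drug enters the central
compartment at a constant rate ``R0 = dose / t_inf`` during each infusion.
Concentration refers to the central compartment (``amount / V1``) and, for
ceftriaxone, to the free (unbound) drug in mg/L.

Micro-constants::

    k10 = CL / V1      elimination
    k12 = Q  / V1      central -> peripheral
    k21 = Q  / V2      peripheral -> central

The hybrid rate constants ``alpha >= beta`` are the roots of
``s**2 - (k10 + k12 + k21) s + k10 k21 = 0``.  For a single infusion the
central concentration is a superposition of two exponentials; multiple doses
superpose linearly.  When ``Q`` is (numerically) zero the model collapses to
a one-compartment model with rate ``k10`` and the code switches to that
analytic limit to avoid a 0/0 in the biexponential coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "StructuralParams",
    "DoseRegimen",
    "HybridConstants",
    "hybrid_constants",
    "conc_profile",
    "ode_oracle",
]

#: below this intercompartmental clearance (L/h) the peripheral compartment
#: is dynamically inert and the one-compartment limit is used
Q_DEGENERATE = 1e-9


@dataclass(frozen=True)
class StructuralParams:
    """Disposition parameters of one subject-episode.

    Parameters
    ----------
    CL : float
        Clearance, L/h. Strictly positive.
    V1 : float
        Central volume of distribution, L. Strictly positive.
    Q : float
        Intercompartmental clearance, L/h. Non-negative; ``Q == 0``
        degenerates to a one-compartment model.
    V2 : float
        Peripheral volume of distribution, L. Strictly positive.
    """

    CL: float
    V1: float
    Q: float
    V2: float

    def __post_init__(self) -> None:
        if not (self.CL > 0 and np.isfinite(self.CL)):
            raise ValueError(f"CL must be finite and > 0, got {self.CL}")
        if not (self.V1 > 0 and np.isfinite(self.V1)):
            raise ValueError(f"V1 must be finite and > 0, got {self.V1}")
        if not (self.Q >= 0 and np.isfinite(self.Q)):
            raise ValueError(f"Q must be finite and >= 0, got {self.Q}")
        if not (self.V2 > 0 and np.isfinite(self.V2)):
            raise ValueError(f"V2 must be finite and > 0, got {self.V2}")

    @property
    def k10(self) -> float:
        return self.CL / self.V1

    @property
    def k12(self) -> float:
        return self.Q / self.V1

    @property
    def k21(self) -> float:
        return self.Q / self.V2


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated intravenous infusion schedule.

    Parameters
    ----------
    dose : float
        Amount per administration, mg.
    t_inf : float
        Infusion duration, h. A 24-h infusion of the daily dose is a
        continuous infusion.
    tau : float
        Inter-dose interval, h. ``t_inf <= tau``.
    n_doses : int
        Number of administrations, starting at t = 0.
    """

    dose: float
    t_inf: float
    tau: float
    n_doses: int = 1

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.t_inf <= 0:
            raise ValueError(f"t_inf must be > 0, got {self.t_inf}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.t_inf > self.tau + 1e-12:
            raise ValueError(f"t_inf ({self.t_inf}) must not exceed tau ({self.tau})")
        if self.n_doses < 1:
            raise ValueError(f"n_doses must be >= 1, got {self.n_doses}")

    @property
    def rate(self) -> float:
        """Infusion rate R0, mg/h."""
        return self.dose / self.t_inf

    def dose_times(self) -> np.ndarray:
        """Start times of the infusions (h), first dose at t = 0."""
        return self.tau * np.arange(self.n_doses, dtype=float)


@dataclass(frozen=True)
class HybridConstants:
    """Hybrid rate constants and bolus partition coefficients.

    ``alpha >= beta`` satisfy ``alpha * beta = k10 * k21`` and
    ``alpha + beta = k10 + k12 + k21``.  ``coef_alpha`` and ``coef_beta``
    are the unit-bolus central-compartment coefficients
    ``(alpha - k21)/(alpha - beta)`` and ``(k21 - beta)/(alpha - beta)``;
    they sum to 1.  In the one-compartment limit ``beta = coef_beta = 0``.
    """

    alpha: float
    beta: float
    coef_alpha: float
    coef_beta: float


def hybrid_constants(params: StructuralParams) -> HybridConstants:
    """Hybrid rate constants of the two-compartment model.

    Uses the numerically stable root pairing (large root from the quadratic
    formula, small root from the product identity).
    """
    k10, k12, k21 = params.k10, params.k12, params.k21
    if params.Q < Q_DEGENERATE:
        return HybridConstants(alpha=k10, beta=0.0, coef_alpha=1.0, coef_beta=0.0)
    s = k10 + k12 + k21
    p = k10 * k21
    disc = max(s * s - 4.0 * p, 0.0)
    alpha = 0.5 * (s + np.sqrt(disc))
    beta = p / alpha
    ca = (alpha - k21) / (alpha - beta)
    cb = (k21 - beta) / (alpha - beta)
    return HybridConstants(alpha=alpha, beta=beta, coef_alpha=ca, coef_beta=cb)


def _infusion_response(
    t: np.ndarray, rate: float, t_inf: float, params: StructuralParams
) -> np.ndarray:
    """Central concentration after one infusion starting at t = 0.

    Valid for all t (returns 0 for t < 0); handles during- and
    post-infusion segments in one expression: with te = clip(t, 0, t_inf),

        C(t) = (R0/V1) * sum_l  c_l/lambda_l * (exp(-lambda_l (t - te))
                                                - exp(-lambda_l t))
    """
    h = hybrid_constants(params)
    t = np.asarray(t, dtype=float)
    tpos = np.maximum(t, 0.0)
    te = np.clip(tpos, 0.0, t_inf)
    out = (h.coef_alpha / h.alpha) * (
        np.exp(-h.alpha * (tpos - te)) - np.exp(-h.alpha * tpos)
    )
    if h.beta > 0.0:
        out += (h.coef_beta / h.beta) * (
            np.exp(-h.beta * (tpos - te)) - np.exp(-h.beta * tpos)
        )
    out *= rate / params.V1
    return np.where(t > 0.0, out, 0.0)


def conc_profile(
    params: StructuralParams, regimen: DoseRegimen, times: np.ndarray
) -> np.ndarray:
    """Free concentration (mg/L) at ``times`` under a repeated-infusion regimen.

    Closed-form biexponential solution, superposed over all administered
    doses. Continuous across the infusion-end boundary and zero at t = 0.

    Parameters
    ----------
    params : StructuralParams
    regimen : DoseRegimen
    times : array-like of float
        Times since the start of the first infusion, h. Must be >= 0.

    Returns
    -------
    numpy.ndarray
        Concentration series, same shape as ``times``.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.zeros_like(times)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if regimen.dose == 0.0:
        return np.zeros_like(times)
    out = np.zeros_like(times)
    for td in regimen.dose_times():
        out += _infusion_response(times - td, regimen.rate, regimen.t_inf, params)
    return out


def ode_oracle(
    params: StructuralParams,
    regimen: DoseRegimen,
    times: np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-10,
) -> np.ndarray:
    """Reference trajectory by numerical integration of the mass-balance ODEs.

    Integrates amounts ``(A1, A2)`` with piecewise-constant infusion input,
    restarting the integrator at every rate discontinuity so the stiff-free
    segments are smooth. Intended as an independent oracle for
    :func:`conc_profile`, not for production simulation.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.zeros_like(times)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")

    k10, k12, k21 = params.k10, params.k12, params.k21
    rate = regimen.rate

    # rate is piecewise constant; breakpoints at every infusion start/stop
    starts = regimen.dose_times()
    breaks = np.unique(np.concatenate([[0.0], starts, starts + regimen.t_inf]))
    t_end = float(max(times.max(), breaks.max()))
    breaks = breaks[breaks < t_end]
    edges = np.concatenate([breaks, [t_end]])

    def rate_at(t: float) -> float:
        on = (t >= starts) & (t < starts + regimen.t_inf)
        return rate * float(np.count_nonzero(on))

    order = np.argsort(times, kind="stable")
    sorted_t = times[order]
    sol = np.zeros((times.size, 2))
    y = np.array([0.0, 0.0])
    for left, right in zip(edges[:-1], edges[1:]):
        r0 = rate_at(0.5 * (left + right))

        def rhs(t, a, r0=r0):
            a1, a2 = a
            return [r0 - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

        mask = (sorted_t > left) & (sorted_t <= right)
        inner = sorted_t[mask]
        # the right edge always carries the state into the next segment
        t_eval = inner if inner.size and inner[-1] >= right else np.append(inner, right)
        res = solve_ivp(
            rhs,
            (left, right),
            y,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            method="DOP853",
        )
        if not res.success:
            raise RuntimeError(
                f"ODE integration failed on [{left}, {right}] for params={params}: "
                f"{res.message}"
            )
        sol[order[mask]] = res.y[:, : inner.size].T
        y = res.y[:, -1]
    out = sol[:, 0] / params.V1
    out[times == 0.0] = 0.0
    return out
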