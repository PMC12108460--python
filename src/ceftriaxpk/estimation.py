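"""Nonlinear mixed-effects estimation by stochastic-approximation EM (SAEM).

The statistical model for episode i with observation vector ``y_i``::

    phi_i = X_i c + eta_i,        eta_i ~ N(0, diag(omega**2))   (log scale)
    y_ij  = f(t_ij; exp(phi_i)) + eps_ij,   eps_ij ~ N(0, sigma**2)

where ``phi_i`` stacks the log parameters (log CL, log V1, log Q, log V2),
``X_i`` is the per-parameter covariate design (intercept = log population
value; continuous covariates enter as ``log(cov / reference)`` so their
coefficients are the power-model exponents; the categorical sex covariate
enters as a 0/1 indicator whose coefficient is the log of the
multiplicative factor) and ``f`` is the closed-form two-compartment
infusion solution.

The E-step samples ``phi_i`` from its conditional posterior with a small
number of Metropolis-Hastings transitions per iteration (one independence
proposal from the prior plus adaptive random-walk proposals), vectorised
across episodes.  The M-step updates the fixed effects by the complete-data
least-squares solution of the linear log-scale model, and ``omega`` and
``sigma`` from stochastically-approximated sufficient statistics.  An
exploratory phase (step size 1) precedes a smoothing phase with step size
``1 / k**step_power``.

The marginal -2 log likelihood is estimated afterwards by importance
sampling with a t proposal centred at the empirical-Bayes posterior.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import t as t_dist

from .cohort import EpisodeRecord
from .population import (
    PARAM_NAMES,
    CovariateEffect,
    Covariates,
    PopulationModel,
)

__all__ = [
    "SaemSettings",
    "FitResult",
    "SelectionReport",
    "BootstrapResult",
    "saem_fit",
    "log_likelihood",
    "compute_bic",
    "select_covariates",
    "default_candidates",
    "bootstrap",
    "ebe_shrinkage",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
_PHI_LO, _PHI_HI = -12.0, 15.0  # log-parameter bounds (guards, never binding)


# ---------------------------------------------------------------------------
# vectorised structural prediction
# ---------------------------------------------------------------------------


def _biexp_terms(CL, V1, Q, V2):
    """alpha, beta, and bolus coefficients for arrays of parameters."""
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    p = k10 * k21
    disc = np.maximum(s * s - 4.0 * p, 0.0)
    alpha = 0.5 * (s + np.sqrt(disc))
    beta = p / alpha
    one_cpt = Q < 1e-9
    denom = np.where(one_cpt, 1.0, alpha - beta)
    ca = np.where(one_cpt, 1.0, (alpha - k21) / denom)
    cb = np.where(one_cpt, 0.0, (k21 - beta) / denom)
    beta_safe = np.maximum(beta, 1e-300)
    return alpha, beta_safe, ca, cb


def _conc_events(CL, V1, Q, V2, t_rel, dur, rate):
    """Central concentration summed over dosing events.

    Parameter arrays have shape ``S``; ``t_rel`` (time since each dose
    start), ``dur`` and ``rate`` have shape ``S + (O, D)`` or broadcast to
    it.  Returns shape ``S + (O,)``.
    """
    alpha, beta, ca, cb = _biexp_terms(CL, V1, Q, V2)
    A = alpha[..., None, None]
    B = beta[..., None, None]
    tpos = np.maximum(t_rel, 0.0)
    te = np.clip(tpos, 0.0, dur)
    term = (ca[..., None, None] / A) * (np.exp(-A * (tpos - te)) - np.exp(-A * tpos))
    term += (cb[..., None, None] / B) * (np.exp(-B * (tpos - te)) - np.exp(-B * tpos))
    active = t_rel > 0.0
    return ((rate / V1[..., None, None]) * term * active).sum(axis=-1)


# ---------------------------------------------------------------------------
# packed dataset
# ---------------------------------------------------------------------------


@dataclass
class _Packed:
    """Dataset in rectangular arrays for vectorised likelihood evaluation."""

    n: int
    dose_t: np.ndarray  # (n, D)
    dose_dur: np.ndarray  # (n, D)
    dose_rate: np.ndarray  # (n, D); 0 where padded
    obs_t: np.ndarray  # (n, O)
    obs_y: np.ndarray  # (n, O); 0 where padded
    obs_mask: np.ndarray  # (n, O) bool
    X: dict[str, np.ndarray]  # per-parameter design (n, q_p)
    n_obs: int
    n_blq_dropped: int
    covariates: list[Covariates]

    def predict(self, phi: np.ndarray) -> np.ndarray:
        """Predicted concentrations (n, O) from log parameters phi (n, 4)."""
        theta = np.exp(phi)
        t_rel = self.obs_t[:, :, None] - self.dose_t[:, None, :]
        return _conc_events(
            theta[:, 0],
            theta[:, 1],
            theta[:, 2],
            theta[:, 3],
            t_rel,
            self.dose_dur[:, None, :],
            self.dose_rate[:, None, :],
        )

    def predict_episode(self, i: int, phi: np.ndarray) -> np.ndarray:
        """Predictions (m, O_i) for episode i under phi (m, 4)."""
        m = self.obs_mask[i]
        theta = np.exp(phi)
        t_rel = self.obs_t[i, m][None, :, None] - self.dose_t[i][None, None, :]
        return _conc_events(
            theta[:, 0],
            theta[:, 1],
            theta[:, 2],
            theta[:, 3],
            t_rel,
            self.dose_dur[i][None, None, :],
            self.dose_rate[i][None, None, :],
        )


def _regressor(effect: CovariateEffect, cov: Covariates) -> float:
    if effect.is_categorical:
        return float(cov.value(effect.covariate))
    return float(np.log(cov.value(effect.covariate) / effect.reference))


def _pack(dataset: list[EpisodeRecord], spec: PopulationModel) -> _Packed:
    if len(dataset) < 1:
        raise ValueError("dataset must contain at least one episode")
    n = len(dataset)
    max_d = max(r.dose_times.size for r in dataset)
    # BLQ policy M1: censored observations are excluded, with a logged count
    kept_t, kept_y, n_blq = [], [], 0
    for r in dataset:
        keep = ~r.obs_blq & np.isfinite(r.obs_conc)
        n_blq += int(np.count_nonzero(~keep & (r.obs_times >= 0)))
        kept_t.append(r.obs_times[keep])
        kept_y.append(r.obs_conc[keep])
    max_o = max(t.size for t in kept_t)
    if max_o == 0:
        raise ValueError("dataset has no quantifiable observations")

    dose_t = np.zeros((n, max_d))
    dose_dur = np.full((n, max_d), 1.0)
    dose_rate = np.zeros((n, max_d))
    obs_t = np.zeros((n, max_o))
    obs_y = np.zeros((n, max_o))
    obs_mask = np.zeros((n, max_o), dtype=bool)
    for i, r in enumerate(dataset):
        d = r.dose_times.size
        dose_t[i, :d] = r.dose_times
        rates = np.maximum(r.dose_rates, 1e-12)
        dose_dur[i, :d] = r.dose_amounts / rates
        dose_rate[i, :d] = r.dose_rates
        o = kept_t[i].size
        obs_t[i, :o] = kept_t[i]
        obs_y[i, :o] = kept_y[i]
        obs_mask[i, :o] = True
        # padded observation slots reuse the first time so predictions stay finite
        if o and o < max_o:
            obs_t[i, o:] = kept_t[i][0]

    covs = [r.covariates for r in dataset]
    X = {}
    for p in PARAM_NAMES:
        cols = [np.ones(n)]
        for eff in spec.covariate_effects:
            if eff.parameter == p:
                cols.append(np.array([_regressor(eff, c) for c in covs]))
        X[p] = np.column_stack(cols)
    if n_blq:
        logger.info("excluded %d BLQ/missing observations (M1 policy)", n_blq)
    return _Packed(
        n=n,
        dose_t=dose_t,
        dose_dur=dose_dur,
        dose_rate=dose_rate,
        obs_t=obs_t,
        obs_y=obs_y,
        obs_mask=obs_mask,
        X=X,
        n_obs=int(obs_mask.sum()),
        n_blq_dropped=n_blq,
        covariates=covs,
    )


# ---------------------------------------------------------------------------
# settings / results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SaemSettings:
    """Tuning of the SAEM run.

    n_explore, n_smooth
        Iterations of the exploratory (step size 1) and smoothing
        (step size ``1/k**step_power``) phases.
    n_mcmc
        Metropolis-Hastings transitions per E-step (first is an
        independence proposal from the prior, the rest random walks).
    seed
        Seed for the fit's random stream; identical seeds give identical
        results.
    fix_omega, fix_sigma
        Optional fixed values (not estimated); ``fix_omega`` maps parameter
        name to SD.
    """

    n_explore: int = 300
    n_smooth: int = 200
    n_mcmc: int = 4
    seed: int = 12345
    step_power: float = 1.0
    omega_floor: float = 1e-3
    sigma_floor: float = 1e-3
    fix_omega: dict[str, float] | None = None
    fix_sigma: float | None = None
    n_post: int = 200  # posterior-summary transitions after the main run


@dataclass
class FitResult:
    """Result of one SAEM fit.

    ``model`` carries the fitted fixed effects, covariate exponents, omega
    and sigma. ``ebes`` are per-episode empirical-Bayes eta estimates
    (conditional modes). ``minus2LL``/``bic`` are filled by
    :func:`log_likelihood` / :func:`compute_bic` (``None`` until computed).
    """

    model: PopulationModel
    ebes: np.ndarray  # (n, 4) conditional modes of eta
    eta_post_mean: np.ndarray  # (n, 4) MCMC posterior means
    eta_post_sd: np.ndarray  # (n, 4) MCMC posterior SDs
    shrinkage: dict[str, float]
    trace: pd.DataFrame
    converged: bool
    n_episodes: int
    n_obs: int
    n_blq_dropped: int
    settings: SaemSettings
    minus2LL: float | None = None
    minus2LL_se: float | None = None
    bic: float | None = None
    rse: dict[str, float] | None = None

    @property
    def theta_hat(self) -> dict[str, float]:
        return dict(self.model.theta_pop)

    @property
    def beta_hat(self) -> dict[str, float]:
        return {
            f"beta_{e.covariate}_{e.parameter}": e.beta
            for e in self.model.covariate_effects
        }

    @property
    def omega_hat(self) -> dict[str, float]:
        return dict(self.model.omega)

    @property
    def sigma_hat(self) -> float:
        return self.model.sigma

    def n_estimated_params(self) -> int:
        k = len(PARAM_NAMES) + len(self.model.covariate_effects) + 1
        if self.settings.fix_omega is None:
            k += len(PARAM_NAMES)
        if self.settings.fix_sigma is not None:
            k -= 1
        return k


def compute_bic(minus2LL: float, k: int, N: int) -> float:
    """Bayesian information criterion ``-2LL + k ln N``.

    ``N`` is the number of random-effect units (episodes).
    """
    if k < 1 or N < 1:
        raise ValueError("k and N must be >= 1")
    return float(minus2LL + k * np.log(N))


# ---------------------------------------------------------------------------
# SAEM core
# ---------------------------------------------------------------------------


def _init_state(packed: _Packed, spec: PopulationModel):
    coef = {}
    for p in PARAM_NAMES:
        q = packed.X[p].shape[1]
        c = np.zeros(q)
        c[0] = np.log(max(spec.theta_pop[p], 1e-6))
        j = 1
        for eff in spec.covariate_effects:
            if eff.parameter == p:
                c[j] = np.log(eff.beta) if eff.is_categorical and eff.beta > 0 else eff.beta
                j += 1
        coef[p] = c
    omega = np.maximum(spec.omega_vector(), 1e-3)
    sigma = spec.sigma
    return coef, omega, sigma


def _mu_matrix(packed: _Packed, coef) -> np.ndarray:
    return np.column_stack([packed.X[p] @ coef[p] for p in PARAM_NAMES])


def _obs_loglik(packed: _Packed, phi: np.ndarray, sigma: float) -> np.ndarray:
    """Per-episode Gaussian observation log likelihood (up to additive const)."""
    pred = packed.predict(phi)
    resid = np.where(packed.obs_mask, packed.obs_y - pred, 0.0)
    nobs = packed.obs_mask.sum(axis=1)
    return -0.5 * (resid**2).sum(axis=1) / sigma**2 - nobs * np.log(sigma)


def _model_from_state(spec: PopulationModel, coef, omega, sigma) -> PopulationModel:
    theta = {}
    effects = []
    for i, p in enumerate(PARAM_NAMES):
        theta[p] = float(np.exp(coef[p][0]))
        j = 1
        for eff in spec.covariate_effects:
            if eff.parameter == p:
                b = float(coef[p][j])
                effects.append(
                    replace(eff, beta=float(np.exp(b)) if eff.is_categorical else b)
                )
                j += 1
    om = {p: float(omega[i]) for i, p in enumerate(PARAM_NAMES)}
    return PopulationModel(
        theta_pop=theta,
        covariate_effects=tuple(effects),
        omega=om,
        sigma=float(sigma),
    )


def saem_fit(
    dataset: list[EpisodeRecord],
    model_spec: PopulationModel,
    settings: SaemSettings | None = None,
    init_etas: np.ndarray | None = None,
) -> FitResult:
    """Fit the population model to a dataset by SAEM.

    ``model_spec`` supplies the model structure (which covariate effects are
    present) and the initial values. ``init_etas`` (n x 4) warm-starts the
    E-step state, e.g. with the empirical-Bayes estimates of a previous fit
    of a nested model; without it the chains start at eta = 0. The fit is
    deterministic for a given ``settings.seed``.
    """
    settings = settings or SaemSettings()
    packed = _pack(dataset, model_spec)
    if packed.n < 2:
        raise ValueError("SAEM needs at least 2 episodes")
    n_par = len(PARAM_NAMES)
    min_obs = int(packed.obs_mask.sum(axis=1).min())
    if min_obs < 1:
        raise ValueError("every episode needs at least one quantifiable observation")
    if min_obs < n_par:
        logger.debug(
            "episodes with fewer observations (%d) than parameters (%d): "
            "individual-level information is sparse",
            min_obs,
            n_par,
        )

    rng = np.random.default_rng(settings.seed)
    coef, omega, sigma = _init_state(packed, model_spec)
    if settings.fix_omega is not None:
        omega = np.array(
            [max(settings.fix_omega.get(p, 0.0), settings.omega_floor) for p in PARAM_NAMES]
        )
    if settings.fix_sigma is not None:
        sigma = max(settings.fix_sigma, settings.sigma_floor)

    mu = _mu_matrix(packed, coef)
    phi = mu.copy()
    if init_etas is not None:
        if init_etas.shape != phi.shape:
            raise ValueError(f"init_etas must have shape {phi.shape}")
        phi = np.clip(mu + init_etas, _PHI_LO, _PHI_HI)
    ll_obs = _obs_loglik(packed, phi, sigma)

    xtx = {p: packed.X[p].T @ packed.X[p] for p in PARAM_NAMES}
    s_xy = {p: packed.X[p].T @ phi[:, i] for i, p in enumerate(PARAM_NAMES)}
    s_yy = np.array([(phi[:, i] ** 2).sum() for i in range(n_par)])
    pred = packed.predict(phi)
    s_res = float(
        ((packed.obs_y - pred) ** 2 * packed.obs_mask).sum()
    )

    # MH kernel scales: one joint random-walk scale plus per-component scales
    step_joint = 0.4
    step_comp = np.full(n_par, 0.4)
    # running per-episode posterior moments for the adaptive correlated kernel
    run_mean = phi.copy()
    run_cov = np.tile(np.diag(np.maximum(omega, 0.05) ** 2), (packed.n, 1, 1))
    chol = np.linalg.cholesky(run_cov)
    step_adapt = 1.1  # ~2.38/sqrt(4), adapted on-line
    n_iter = settings.n_explore + settings.n_smooth
    trace_rows = []

    for k in range(n_iter):
        # ----- E-step: MH transitions on phi, vectorised across episodes
        for m in range(settings.n_mcmc):
            if m == 0:
                # independence proposal from the prior
                prop = mu + rng.standard_normal((packed.n, n_par)) * omega
                prop = np.clip(prop, _PHI_LO, _PHI_HI)
                ll_prop = _obs_loglik(packed, prop, sigma)
                log_acc = ll_prop - ll_obs  # prior cancels with the proposal
                accept = np.log(rng.random(packed.n)) < log_acc
                phi = np.where(accept[:, None], prop, phi)
                ll_obs = np.where(accept, ll_prop, ll_obs)
            elif m == 1:
                # joint random walk
                prop = phi + rng.standard_normal((packed.n, n_par)) * (step_joint * omega)
                prop = np.clip(prop, _PHI_LO, _PHI_HI)
                ll_prop = _obs_loglik(packed, prop, sigma)
                lp_curr = -0.5 * (((phi - mu) / omega) ** 2).sum(axis=1)
                lp_prop = -0.5 * (((prop - mu) / omega) ** 2).sum(axis=1)
                log_acc = ll_prop + lp_prop - ll_obs - lp_curr
                accept = np.log(rng.random(packed.n)) < log_acc
                step_joint = float(
                    np.clip(step_joint * np.exp(0.05 * (accept.mean() - 0.35)), 0.02, 2.0)
                )
                phi = np.where(accept[:, None], prop, phi)
                ll_obs = np.where(accept, ll_prop, ll_obs)
            elif m == 2:
                # correlated random walk from the running posterior covariance
                z = rng.standard_normal((packed.n, n_par))
                prop = phi + step_adapt * np.einsum("nij,nj->ni", chol, z)
                prop = np.clip(prop, _PHI_LO, _PHI_HI)
                ll_prop = _obs_loglik(packed, prop, sigma)
                lp_curr = -0.5 * (((phi - mu) / omega) ** 2).sum(axis=1)
                lp_prop = -0.5 * (((prop - mu) / omega) ** 2).sum(axis=1)
                accept = np.log(rng.random(packed.n)) < (
                    ll_prop + lp_prop - ll_obs - lp_curr
                )
                step_adapt = float(
                    np.clip(step_adapt * np.exp(0.05 * (accept.mean() - 0.3)), 0.05, 3.0)
                )
                phi = np.where(accept[:, None], prop, phi)
                ll_obs = np.where(accept, ll_prop, ll_obs)
            else:
                # componentwise random walk (one coordinate at a time)
                for j in range(n_par):
                    prop = phi.copy()
                    prop[:, j] = np.clip(
                        phi[:, j]
                        + rng.standard_normal(packed.n) * (step_comp[j] * omega[j]),
                        _PHI_LO,
                        _PHI_HI,
                    )
                    ll_prop = _obs_loglik(packed, prop, sigma)
                    lp_diff = -0.5 * (
                        ((prop[:, j] - mu[:, j]) / omega[j]) ** 2
                        - ((phi[:, j] - mu[:, j]) / omega[j]) ** 2
                    )
                    accept = np.log(rng.random(packed.n)) < (ll_prop - ll_obs + lp_diff)
                    step_comp[j] = float(
                        np.clip(
                            step_comp[j] * np.exp(0.05 * (accept.mean() - 0.4)),
                            0.02,
                            3.0,
                        )
                    )
                    phi = np.where(accept[:, None], prop, phi)
                    ll_obs = np.where(accept, ll_prop, ll_obs)

        # ----- update running posterior moments / proposal Cholesky
        w_ad = 0.02 if k < settings.n_explore else 0.01
        dphi = phi - run_mean
        run_mean += w_ad * dphi
        run_cov += w_ad * (
            np.einsum("ni,nj->nij", dphi, dphi) - run_cov
        )
        if k % 20 == 19:
            try:
                chol = np.linalg.cholesky(
                    run_cov + 1e-6 * np.eye(n_par)[None, :, :]
                )
            except np.linalg.LinAlgError:  # pragma: no cover - defensive
                pass

        # ----- stochastic approximation of sufficient statistics
        gamma = 1.0 if k < settings.n_explore else 1.0 / (k - settings.n_explore + 1) ** settings.step_power
        pred = packed.predict(phi)
        res2 = float(((packed.obs_y - pred) ** 2 * packed.obs_mask).sum())
        s_res += gamma * (res2 - s_res)
        for i, p in enumerate(PARAM_NAMES):
            s_xy[p] = s_xy[p] + gamma * (packed.X[p].T @ phi[:, i] - s_xy[p])
            s_yy[i] = s_yy[i] + gamma * ((phi[:, i] ** 2).sum() - s_yy[i])

        # ----- M-step (with simulated annealing on the variances during the
        # exploratory phase: a variance may shrink by at most 5% per
        # iteration, which prevents premature collapse of omega and sigma)
        anneal = 0.95 if k < settings.n_explore else 0.0
        for i, p in enumerate(PARAM_NAMES):
            c = np.linalg.solve(xtx[p], s_xy[p])
            coef[p] = c
            if settings.fix_omega is None:
                var = max((s_yy[i] - c @ s_xy[p]) / packed.n, settings.omega_floor**2)
                omega[i] = np.sqrt(max(var, anneal * omega[i] ** 2))
        if settings.fix_sigma is None:
            var = max(s_res / packed.n_obs, settings.sigma_floor**2)
            sigma = np.sqrt(max(var, anneal * sigma**2))
        mu = _mu_matrix(packed, coef)
        ll_obs = _obs_loglik(packed, phi, sigma)

        row = {"iteration": k, "sigma": sigma}
        for i, p in enumerate(PARAM_NAMES):
            row[f"theta_{p}"] = float(np.exp(coef[p][0]))
            row[f"omega_{p}"] = float(omega[i])
        trace_rows.append(row)

    trace = pd.DataFrame(trace_rows)
    converged = _check_convergence(trace)
    if not converged:
        warnings.warn(
            "SAEM trace did not stabilise; increase n_explore/n_smooth",
            RuntimeWarning,
            stacklevel=2,
        )

    # ----- posterior summaries of eta at the final parameter values
    post_mean = np.zeros_like(phi)
    post_m2 = np.zeros_like(phi)
    count = 0
    for _ in range(settings.n_post):
        for j in range(n_par):
            prop = phi.copy()
            prop[:, j] = np.clip(
                phi[:, j] + rng.standard_normal(packed.n) * (step_comp[j] * omega[j]),
                _PHI_LO,
                _PHI_HI,
            )
            ll_prop = _obs_loglik(packed, prop, sigma)
            lp_diff = -0.5 * (
                ((prop[:, j] - mu[:, j]) / omega[j]) ** 2
                - ((phi[:, j] - mu[:, j]) / omega[j]) ** 2
            )
            accept = np.log(rng.random(packed.n)) < (ll_prop - ll_obs + lp_diff)
            phi = np.where(accept[:, None], prop, phi)
            ll_obs = np.where(accept, ll_prop, ll_obs)
        count += 1
        delta = (phi - mu) - post_mean
        post_mean += delta / count
        post_m2 += delta * ((phi - mu) - post_mean)
    post_sd = np.sqrt(post_m2 / max(count - 1, 1))
    post_sd = np.maximum(post_sd, 1e-6)

    ebes = _conditional_modes(packed, mu, omega, sigma, start=post_mean)
    model = _model_from_state(model_spec, coef, omega, sigma)
    shrink = ebe_shrinkage(ebes, {p: float(omega[i]) for i, p in enumerate(PARAM_NAMES)})

    return FitResult(
        model=model,
        ebes=ebes,
        eta_post_mean=post_mean,
        eta_post_sd=post_sd,
        shrinkage=shrink,
        trace=trace,
        converged=converged,
        n_episodes=packed.n,
        n_obs=packed.n_obs,
        n_blq_dropped=packed.n_blq_dropped,
        settings=settings,
    )


def _check_convergence(trace: pd.DataFrame, rel_tol: float = 0.05) -> bool:
    """Stability of theta/sigma over the last two fifths of the smoothing run."""
    n = len(trace)
    if n < 20:
        return False
    a = trace.iloc[int(0.6 * n) : int(0.8 * n)]
    b = trace.iloc[int(0.8 * n) :]
    for col in trace.columns:
        if col == "iteration" or col.startswith("omega"):
            continue
        ma, mb = a[col].mean(), b[col].mean()
        scale = max(abs(ma), abs(mb), 1e-6)
        if abs(ma - mb) / scale > rel_tol:
            return False
    return True


def _conditional_modes(packed, mu, omega, sigma, start) -> np.ndarray:
    """Per-episode MAP eta estimates (empirical-Bayes estimates)."""
    ebes = np.zeros_like(mu)
    for i in range(packed.n):
        y = packed.obs_y[i, packed.obs_mask[i]]

        def neg_post(eta, i=i, y=y):
            phi_i = np.clip(mu[i] + eta, _PHI_LO, _PHI_HI)
            pred = packed.predict_episode(i, phi_i[None, :])[0]
            return 0.5 * ((y - pred) ** 2).sum() / sigma**2 + 0.5 * (
                (eta / omega) ** 2
            ).sum()

        res = minimize(neg_post, start[i], method="Nelder-Mead",
                       options={"maxiter": 250, "xatol": 1e-5, "fatol": 1e-8})
        ebes[i] = res.x
    return ebes


def ebe_shrinkage(ebes: np.ndarray, omega_hat: dict[str, float]) -> dict[str, float]:
    """Eta-shrinkage ``(1 - SD(eta_hat)/omega) * 100`` per parameter.

    Returns NaN for parameters with omega = 0 (shrinkage undefined).
    """
    ebes = np.asarray(ebes, dtype=float)
    if ebes.ndim != 2 or ebes.shape[0] < 2:
        raise ValueError("need EBEs for at least 2 episodes")
    out = {}
    for i, p in enumerate(PARAM_NAMES):
        om = omega_hat.get(p, 0.0)
        if om <= 0:
            out[p] = float("nan")
        else:
            out[p] = float((1.0 - np.std(ebes[:, i], ddof=1) / om) * 100.0)
    return out


# ---------------------------------------------------------------------------
# marginal likelihood by importance sampling
# ---------------------------------------------------------------------------


def _laplace_cov(neg_post, mode: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Inverse Hessian of the negative log posterior at the mode (central FD)."""
    d = mode.size
    H = np.zeros((d, d))
    f0 = neg_post(mode)
    steps = np.full(d, h)
    for a in range(d):
        ea = np.zeros(d)
        ea[a] = steps[a]
        fpp = neg_post(mode + ea)
        fmm = neg_post(mode - ea)
        H[a, a] = (fpp - 2 * f0 + fmm) / steps[a] ** 2
        for b in range(a + 1, d):
            eb = np.zeros(d)
            eb[b] = steps[b]
            H[a, b] = H[b, a] = (
                neg_post(mode + ea + eb)
                - neg_post(mode + ea - eb)
                - neg_post(mode - ea + eb)
                + neg_post(mode - ea - eb)
            ) / (4 * steps[a] * steps[b])
    # symmetrise and floor eigenvalues for a proper covariance
    vals, vecs = np.linalg.eigh(0.5 * (H + H.T))
    vals = np.maximum(vals, 1e-6)
    return (vecs / vals) @ vecs.T


def log_likelihood(
    fit: FitResult,
    dataset: list[EpisodeRecord],
    n_is: int = 1000,
    seed: int = 0,
    df: float = 5.0,
    scale_inflation: float = 1.2,
) -> FitResult:
    """Estimate -2 log marginal likelihood by importance sampling.

    Per episode the proposal is a multivariate t(df) centred at the
    conditional mode of eta with an inflated Laplace (inverse-Hessian)
    covariance, so the weights stay well behaved even for correlated
    individual posteriors.  Parameters with omega = 0 are held at eta = 0
    and not integrated.  Fills ``fit.minus2LL``, ``fit.minus2LL_se`` and
    ``fit.bic`` and returns the fit.
    """
    if n_is < 10:
        raise ValueError("n_is must be >= 10")
    packed = _pack(dataset, fit.model)
    model = fit.model
    omega_raw = model.omega_vector()
    active = omega_raw > 1e-8  # omega = 0: eta fixed at 0, not integrated
    omega = omega_raw[active]
    d = int(active.sum())
    sigma = model.sigma
    coef_mu = _mu_from_model(packed, model)

    rng = np.random.default_rng(seed)
    total_ll = 0.0
    total_var = 0.0
    for i in range(packed.n):
        y = packed.obs_y[i, packed.obs_mask[i]]

        def neg_post(eta_act, i=i, y=y):
            eta = np.zeros(len(PARAM_NAMES))
            eta[active] = eta_act
            phi = np.clip(coef_mu[i] + eta, _PHI_LO, _PHI_HI)
            pred = packed.predict_episode(i, phi[None, :])[0]
            return 0.5 * ((y - pred) ** 2).sum() / sigma**2 + 0.5 * (
                (eta_act / omega) ** 2
            ).sum()

        # fit.ebes are conditional modes at the fitted parameters; a short
        # polish suffices (and re-centres if fit.model was swapped)
        mode = minimize(
            neg_post,
            fit.ebes[i, active],
            method="Nelder-Mead",
            options={"maxiter": 80, "xatol": 1e-5, "fatol": 1e-8},
        ).x
        cov = scale_inflation**2 * _laplace_cov(neg_post, mode)
        L = np.linalg.cholesky(cov)

        for attempt in range(2):
            z = rng.standard_normal((n_is, d))
            u = rng.chisquare(df, size=n_is)
            x = z @ L.T * np.sqrt(df / u)[:, None]  # multivariate t deviates
            eta_act = mode + x
            eta = np.zeros((n_is, len(PARAM_NAMES)))
            eta[:, active] = eta_act
            phi = np.clip(coef_mu[i] + eta, _PHI_LO, _PHI_HI)
            pred = packed.predict_episode(i, phi)
            ll_y = (
                -0.5 * ((y - pred) ** 2).sum(axis=1) / sigma**2
                - y.size * (np.log(sigma) + 0.5 * _LOG2PI)
            )
            lp = (-0.5 * (eta_act / omega) ** 2 - np.log(omega) - 0.5 * _LOG2PI).sum(
                axis=1
            )
            # multivariate t log density
            quad = np.einsum("ij,ij->i", x @ np.linalg.inv(cov), x)
            from scipy.special import gammaln

            lq = (
                gammaln((df + d) / 2)
                - gammaln(df / 2)
                - 0.5 * d * np.log(df * np.pi)
                - 0.5 * np.linalg.slogdet(cov)[1]
                - 0.5 * (df + d) * np.log1p(quad / df)
            )
            logw = ll_y + lp - lq
            if np.isfinite(logw).any():
                break
            L = L * 4.0  # degenerate proposal: widen and retry
            cov = cov * 16.0
            warnings.warn(
                f"degenerate importance proposal for episode {i}; widening",
                RuntimeWarning,
                stacklevel=2,
            )
        lmax = logw.max()
        w = np.exp(logw - lmax)
        mean_w = w.mean()
        total_ll += lmax + np.log(mean_w)
        # delta-method variance of log-mean-weight
        total_var += w.var(ddof=1) / (n_is * mean_w**2)

    fit.minus2LL = float(-2.0 * total_ll)
    fit.minus2LL_se = float(2.0 * np.sqrt(total_var))
    fit.bic = compute_bic(fit.minus2LL, fit.n_estimated_params(), packed.n)
    return fit


def _mu_from_model(packed: _Packed, model: PopulationModel) -> np.ndarray:
    coef = {}
    for p in PARAM_NAMES:
        c = [np.log(model.theta_pop[p])]
        for eff in model.covariate_effects:
            if eff.parameter == p:
                c.append(np.log(eff.beta) if eff.is_categorical else eff.beta)
        coef[p] = np.array(c)
    return _mu_matrix(packed, coef)


# ---------------------------------------------------------------------------
# covariate selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionReport:
    """Step log and outcome of forward-inclusion / backward-deletion."""

    steps: list[dict]
    final_model: PopulationModel
    final_fit: FitResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


_REFERENCE_MEDIANS = {"crcl": 59.5, "bmi": 29.3, "age": 77.0, "weight": 90.0}


def default_candidates(
    covariates: tuple[str, ...] = ("crcl", "age", "weight", "bmi", "sex"),
    parameters: tuple[str, ...] = PARAM_NAMES,
) -> list[CovariateEffect]:
    """The full candidate grid: each covariate on each disposition parameter."""
    out = []
    for cov in covariates:
        for p in parameters:
            if cov == "sex":
                out.append(CovariateEffect(p, cov, 1.0))
            else:
                out.append(CovariateEffect(p, cov, 0.0, _REFERENCE_MEDIANS[cov]))
    return out


def _strip_effect(model: PopulationModel, eff: CovariateEffect) -> PopulationModel:
    return replace(
        model,
        covariate_effects=tuple(
            e
            for e in model.covariate_effects
            if not (e.parameter == eff.parameter and e.covariate == eff.covariate)
        ),
    )


def select_covariates(
    dataset: list[EpisodeRecord],
    base_spec: PopulationModel,
    candidates: list[CovariateEffect] | None = None,
    settings: SaemSettings | None = None,
    n_is: int = 1000,
    forward_threshold: float = 3.84,
    backward_threshold: float = 3.84,
) -> SelectionReport:
    """Stepwise forward-inclusion / backward-deletion covariate search.

    A candidate is accepted in the forward phase when adding it decreases
    -2LL by at least ``forward_threshold`` (chi-squared 1 df, p <= 0.05),
    decreases the BIC, and reduces the between-subject SD of the parameter
    it acts on.  Backward deletion removes covariates whose deletion
    worsens -2LL by less than ``backward_threshold``.

    Because both the SAEM estimates and the importance-sampled -2LL are
    stochastic, each forward step evaluates all models under common random
    numbers: candidate fits are warm-started from the current model's
    solution with the same SAEM seed, -2LL uses one shared
    importance-sampling seed per step, and the current model is re-fitted
    under the same scheme (plus a rescue refit warm-started from the best
    candidate's solution) so fit-quality noise largely cancels in the
    likelihood differences.
    """
    settings = settings or SaemSettings()
    candidates = default_candidates() if candidates is None else list(candidates)

    current_spec = base_spec
    current = saem_fit(dataset, current_spec, settings)
    refit_settings = replace(
        settings,
        n_explore=max(50, settings.n_explore // 3),
        n_smooth=max(80, settings.n_smooth // 2),
    )
    steps: list[dict] = []

    def same_effect(a: CovariateEffect, b: CovariateEffect) -> bool:
        return a.parameter == b.parameter and a.covariate == b.covariate

    def warm_fit(
        spec: PopulationModel, step_seed: int, is_seed: int, etas=None
    ) -> FitResult:
        fit = saem_fit(
            dataset, spec, replace(refit_settings, seed=step_seed), init_etas=etas
        )
        return log_likelihood(fit, dataset, n_is=n_is, seed=is_seed)

    remaining = list(candidates)
    step_idx = 0
    while remaining:
        step_seed = settings.seed + 9001 + 131 * step_idx
        is_seed = settings.seed + 7919 + 131 * step_idx
        base_refit = warm_fit(current.model, step_seed, is_seed, etas=current.ebes)
        # the incoming fit of the same model is a second base-side attempt:
        # keep whichever attempt found the better likelihood
        current = log_likelihood(current, dataset, n_is=n_is, seed=is_seed)
        if current.minus2LL < base_refit.minus2LL:
            base_refit = current
        base_m2ll = base_refit.minus2LL

        evaluated = []
        for cand in remaining:
            trial = warm_fit(
                current.model.with_effect(cand), step_seed, is_seed,
                etas=current.ebes,
            )
            evaluated.append((cand, trial))
        best_cand, best_trial = max(evaluated, key=lambda e: -e[1].minus2LL)

        # rescue: if the base refit got stuck, a base fit warm-started from
        # the best candidate's solution (effect stripped) recovers it; only
        # needed when the best candidate is about to clear the threshold
        if base_m2ll - best_trial.minus2LL >= forward_threshold:
            rescue = warm_fit(
                _strip_effect(best_trial.model, best_cand), step_seed, is_seed,
                etas=best_trial.ebes,
            )
            if rescue.minus2LL < base_m2ll:
                base_refit, base_m2ll = rescue, rescue.minus2LL
        k_base = base_refit.n_estimated_params()
        bic_base = compute_bic(base_m2ll, k_base, base_refit.n_episodes)

        accepted_cand = None
        for cand, trial in evaluated:
            d_m2ll = base_m2ll - trial.minus2LL
            d_bic = compute_bic(
                trial.minus2LL, trial.n_estimated_params(), trial.n_episodes
            ) - bic_base
            d_bsv = (
                trial.model.omega[cand.parameter]
                - base_refit.model.omega[cand.parameter]
            )
            ok = d_m2ll >= forward_threshold and d_bic < 0 and d_bsv < 0
            steps.append(
                {
                    "phase": "forward",
                    "candidate": f"{cand.covariate}->{cand.parameter}",
                    "delta_minus2LL": float(d_m2ll),
                    "delta_BIC": float(d_bic),
                    "delta_BSV": float(d_bsv),
                    "accepted": False,
                }
            )
            if cand is best_cand and ok:
                accepted_cand = cand
        if accepted_cand is None:
            current = base_refit
            break
        steps[-len(evaluated) + [c for c, _ in evaluated].index(accepted_cand)][
            "accepted"
        ] = True
        current = best_trial
        current_spec = current.model
        remaining = [c for c in remaining if not same_effect(c, accepted_cand)]
        step_idx += 1

    # backward deletion (same warm-start / common-random-number scheme;
    # the current model is re-fitted under the step's seed so both sides of
    # each deletion are compared at matched fit quality)
    changed = True
    while changed and current.model.covariate_effects:
        changed = False
        step_seed = settings.seed + 9001 + 131 * step_idx
        is_seed = settings.seed + 7919 + 131 * step_idx
        current_refit = warm_fit(
            current.model, step_seed, is_seed, etas=current.ebes
        )
        current = log_likelihood(current, dataset, n_is=n_is, seed=is_seed)
        if current_refit.minus2LL < current.minus2LL:
            current = current_refit
        results = []
        for eff in current.model.covariate_effects:
            reduced = warm_fit(
                _strip_effect(current.model, eff), step_seed, is_seed,
                etas=current.ebes,
            )
            worsening = reduced.minus2LL - current.minus2LL
            if worsening < backward_threshold:
                # deletion imminent: make sure the full model is not merely
                # stuck by refitting it warm from the reduced solution
                rescue = warm_fit(
                    reduced.model.with_effect(
                        next(
                            e
                            for e in current.model.covariate_effects
                            if e.parameter == eff.parameter
                            and e.covariate == eff.covariate
                        )
                    ),
                    step_seed,
                    is_seed,
                    etas=reduced.ebes,
                )
                if rescue.minus2LL < current.minus2LL:
                    current = rescue
                    worsening = reduced.minus2LL - current.minus2LL
            results.append((eff, reduced, worsening))
            steps.append(
                {
                    "phase": "backward",
                    "candidate": f"{eff.covariate}->{eff.parameter}",
                    "delta_minus2LL": float(worsening),
                    "delta_BIC": float(
                        compute_bic(
                            reduced.minus2LL,
                            reduced.n_estimated_params(),
                            reduced.n_episodes,
                        )
                        - compute_bic(
                            current.minus2LL,
                            current.n_estimated_params(),
                            current.n_episodes,
                        )
                    ),
                    "delta_BSV": float("nan"),
                    "accepted": False,
                }
            )
        removable = [r for r in results if r[2] < backward_threshold]
        if removable:
            eff, reduced, worsening = min(removable, key=lambda r: r[2])
            for s in reversed(steps):
                if s["phase"] == "backward" and s["candidate"] == f"{eff.covariate}->{eff.parameter}":
                    s["accepted"] = True  # accepted = deletion performed
                    break
            current = reduced
            changed = True
            step_idx += 1

    if current.minus2LL is None:
        current = log_likelihood(
            current, dataset, n_is=n_is, seed=settings.seed + 7919
        )
    return SelectionReport(steps=steps, final_model=current.model, final_fit=current)


# ---------------------------------------------------------------------------
# nonparametric bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Per-parameter bootstrap summary (median, IQR, SD, RSE%)."""

    summary: pd.DataFrame
    replicates: pd.DataFrame
    n_requested: int
    n_failed: int

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / self.n_requested


def _fit_to_row(fit: FitResult) -> dict[str, float]:
    row = {f"theta_{p}": fit.model.theta_pop[p] for p in PARAM_NAMES}
    row.update(fit.beta_hat)
    row.update({f"omega_{p}": fit.model.omega[p] for p in PARAM_NAMES})
    row["sigma"] = fit.model.sigma
    return row


def bootstrap(
    dataset: list[EpisodeRecord],
    final_spec: PopulationModel,
    n_iter: int = 1000,
    seed: int = 0,
    settings: SaemSettings | None = None,
    indices_list: list[np.ndarray] | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample episodes with replacement and refit.

    Reports per-parameter median, IQR, SD and RSE% over successful
    replicates. Replicates whose fit raises or fails to converge are
    excluded and counted; more than 20% failures triggers a warning.
    ``indices_list`` overrides the random resampling (e.g. the identity
    permutation reproduces the point fit).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    settings = settings or SaemSettings()
    n = len(dataset)
    rng = np.random.default_rng(seed)
    if indices_list is None:
        indices_list = [rng.integers(0, n, size=n) for _ in range(n_iter)]
    elif len(indices_list) != n_iter:
        raise ValueError("indices_list length must equal n_iter")

    rows, n_failed = [], 0
    for b, idx in enumerate(indices_list):
        resampled = [dataset[j] for j in idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                # all replicates share the point fit's SAEM seed (common
                # random numbers: spread reflects resampling, not MC noise)
                fit = saem_fit(resampled, final_spec, settings)
        except Exception as exc:  # pragma: no cover - defensive
            logger.info("bootstrap replicate %d failed: %s", b, exc)
            n_failed += 1
            continue
        rows.append(_fit_to_row(fit))
    if n_failed > 0.2 * n_iter:
        warnings.warn(
            f"{n_failed}/{n_iter} bootstrap replicates failed",
            RuntimeWarning,
            stacklevel=2,
        )
    reps = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "median": reps.median(),
            "q25": reps.quantile(0.25),
            "q75": reps.quantile(0.75),
            "sd": reps.std(ddof=1),
            "mean": reps.mean(),
        }
    )
    summary["rse_pct"] = 100.0 * summary["sd"] / summary["mean"].abs()
    return BootstrapResult(
        summary=summary, replicates=reps, n_requested=n_iter, n_failed=n_failed
    )
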