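"""SAEM estimation, marginal likelihood, bootstrap and shrinkage."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import least_squares

import ceftriaxpk as cpk
from ceftriaxpk import (
    DoseRegimen,
    PopulationModel,
    SaemSettings,
    bootstrap,
    compute_bic,
    conc_profile,
    ebe_shrinkage,
    individual_params,
    log_likelihood,
    saem_fit,
)


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


class TestBic:
    def test_formula(self):
        assert compute_bic(100.0, 5, 24) == pytest.approx(100 + 5 * np.log(24))
        assert compute_bic(100.0, 5, 24) == pytest.approx(115.89, abs=0.01)

    def test_single_subject_reduces_to_minus2ll(self):
        assert compute_bic(123.4, 7, 1) == 123.4

    def test_extra_parameter_costs_log_n(self):
        assert compute_bic(50.0, 6, 24) - compute_bic(50.0, 5, 24) == pytest.approx(
            np.log(24)
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_bic(10.0, 0, 24)


class TestShrinkage:
    def test_all_zero_ebes_give_full_shrinkage(self):
        sh = ebe_shrinkage(np.zeros((10, 4)), {"CL": 0.5, "V1": 0.5, "Q": 0.5, "V2": 0.5})
        assert all(v == pytest.approx(100.0) for v in sh.values())

    def test_sd_equal_omega_gives_zero(self):
        rng = np.random.default_rng(0)
        e = rng.standard_normal((20000, 4)) * 0.5
        e = (e - e.mean(0)) / e.std(0, ddof=1) * 0.5
        sh = ebe_shrinkage(e, {"CL": 0.5, "V1": 0.5, "Q": 0.5, "V2": 0.5})
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in sh.values())

    def test_zero_omega_not_applicable(self):
        sh = ebe_shrinkage(np.zeros((5, 4)), {"CL": 0.0, "V1": 1, "Q": 1, "V2": 1})
        assert np.isnan(sh["CL"])


class TestSaemFit:
    def test_determinism_under_fixed_seed(self, final_model, sparse_dataset):
        s = SaemSettings(n_explore=60, n_smooth=60, seed=3)
        a = saem_fit(sparse_dataset, final_model, s)
        b = saem_fit(sparse_dataset, final_model, s)
        assert a.theta_hat == b.theta_hat
        assert a.omega_hat == b.omega_hat
        assert np.array_equal(a.ebes, b.ebes)

    def test_rich_design_recovers_fixed_effects(self, rich_fit):
        """All four disposition parameters within 15% of generating truth."""
        _, fit = rich_fit
        truth = {"CL": 11.57, "V1": 43.6, "Q": 19.8, "V2": 40.94}
        for p, v in truth.items():
            assert fit.theta_hat[p] == pytest.approx(v, rel=0.15)
        assert fit.converged

    def test_rich_design_cl_shrinkage_low(self, rich_fit):
        _, fit = rich_fit
        assert fit.shrinkage["CL"] < 20.0

    def test_degenerate_no_bsv_matches_pooled_nls(self):
        """With omega = 0 data and sigma fixed, SAEM reduces to pooled NLS."""
        truth = PopulationModel(
            theta_pop={"CL": 11.57, "V1": 43.6, "Q": 19.8, "V2": 40.94}, sigma=0.5
        )
        design = cpk.StudyDesign(
            n_episodes=30, sampling_offsets=(0.0, 0.5, 1.5, 2.0, 4.0, 6.0, 9.0)
        )
        data = cpk.generate_dataset(design, truth, np.random.default_rng(3))

        def resid(logth):
            p = cpk.StructuralParams(*np.exp(logth))
            out = []
            for r in data:
                reg = DoseRegimen(
                    r.dose_amounts[0],
                    r.dose_amounts[0] / r.dose_rates[0],
                    r.dose_times[1] - r.dose_times[0],
                    len(r.dose_times),
                )
                keep = ~r.obs_blq
                out.append(
                    r.obs_conc[keep] - conc_profile(p, reg, r.obs_times)[keep]
                )
            return np.concatenate(out)

        nls = np.exp(least_squares(resid, np.log([10, 40, 20, 40])).x)
        fit = saem_fit(
            data,
            truth,
            SaemSettings(
                seed=2,
                fix_omega={p: 1e-4 for p in ("CL", "V1", "Q", "V2")},
                fix_sigma=0.5,
                n_explore=300,
                n_smooth=300,
            ),
        )
        est = np.array([fit.theta_hat[p] for p in ("CL", "V1", "Q", "V2")])
        assert est == pytest.approx(nls, rel=0.01)

    def test_too_few_episodes_rejected(self, final_model, sparse_dataset):
        with pytest.raises(ValueError):
            saem_fit(sparse_dataset[:1], final_model)


class TestLogLikelihood:
    def test_matches_quadrature_on_single_random_effect(self, final_model):
        """1-D quadrature oracle: omega on CL only, two episodes."""
        data = cpk.generate_dataset(
            cpk.StudyDesign(), final_model, np.random.default_rng(5)
        )[:2]
        m1 = PopulationModel(
            theta_pop=final_model.theta_pop,
            omega={"CL": 0.4, "V1": 0, "Q": 0, "V2": 0},
            sigma=1.0,
        )
        fit = saem_fit(
            data,
            m1,
            SaemSettings(
                seed=1,
                fix_omega={"CL": 0.4, "V1": 1e-6, "Q": 1e-6, "V2": 1e-6},
                fix_sigma=1.0,
                n_explore=50,
                n_smooth=50,
            ),
        )
        fit.model = m1
        fit = log_likelihood(fit, data, n_is=8000, seed=9)

        def marginal(rec):
            reg = DoseRegimen(
                rec.dose_amounts[0],
                rec.dose_amounts[0] / rec.dose_rates[0],
                rec.dose_times[1] - rec.dose_times[0],
                len(rec.dose_times),
            )
            keep = ~rec.obs_blq
            y, t = rec.obs_conc[keep], rec.obs_times[keep]

            def integrand(e):
                p = individual_params(m1, rec.covariates, {"CL": e})
                pred = conc_profile(p, reg, t)
                return (
                    np.exp(-0.5 * ((y - pred) ** 2).sum())
                    * (2 * np.pi) ** (-y.size / 2)
                    * np.exp(-0.5 * (e / 0.4) ** 2)
                    / (0.4 * np.sqrt(2 * np.pi))
                )

            return quad(integrand, -4, 4, limit=200)[0]

        oracle = -2 * sum(np.log(marginal(r)) for r in data)
        assert fit.minus2LL == pytest.approx(oracle, abs=max(3 * fit.minus2LL_se, 1.0))

    def test_duplicated_dataset_doubles_minus2ll(self, final_model, sparse_dataset):
        fit = saem_fit(
            sparse_dataset, final_model, SaemSettings(n_explore=80, n_smooth=80, seed=1)
        )
        fit = log_likelihood(fit, sparse_dataset, n_is=1000, seed=3)
        doubled = sparse_dataset + [
            cpk.EpisodeRecord(
                r.episode_id + "b", r.covariates, r.dose_times, r.dose_amounts,
                r.dose_rates, r.obs_times, r.obs_conc, r.obs_blq,
            )
            for r in sparse_dataset
        ]
        fit2 = saem_fit(
            doubled, final_model, SaemSettings(n_explore=80, n_smooth=80, seed=1)
        )
        fit2.model = fit.model  # same parameter values -> additivity
        fit2.ebes = np.vstack([fit.ebes] * 2)
        fit2.eta_post_mean = np.vstack([fit.eta_post_mean] * 2)
        fit2.eta_post_sd = np.vstack([fit.eta_post_sd] * 2)
        fit2 = log_likelihood(fit2, doubled, n_is=1000, seed=3)
        se = np.hypot(2 * fit.minus2LL_se, fit2.minus2LL_se)
        assert fit2.minus2LL == pytest.approx(2 * fit.minus2LL, abs=max(4 * se, 2.0))

    def test_variance_shrinks_with_n_is(self, final_model, sparse_dataset):
        fit = saem_fit(
            sparse_dataset, final_model, SaemSettings(n_explore=80, n_smooth=80, seed=1)
        )
        small = [
            log_likelihood(fit, sparse_dataset, n_is=100, seed=s).minus2LL
            for s in range(6)
        ]
        large = [
            log_likelihood(fit, sparse_dataset, n_is=2000, seed=s).minus2LL
            for s in range(6)
        ]
        assert np.std(large) < np.std(small)


class TestBootstrap:
    def test_identity_resample_reproduces_point_fit(self, final_model, sparse_dataset):
        s = SaemSettings(n_explore=60, n_smooth=60, seed=4)
        point = saem_fit(sparse_dataset, final_model, s)
        res = bootstrap(
            sparse_dataset,
            final_model,
            n_iter=1,
            seed=0,
            settings=s,
            indices_list=[np.arange(len(sparse_dataset))],
        )
        assert res.replicates.loc[0, "theta_CL"] == pytest.approx(
            point.theta_hat["CL"], rel=1e-12
        )
        assert res.n_failed == 0

    def test_fixed_seed_identical_resamples(self, final_model, sparse_dataset):
        s = SaemSettings(n_explore=40, n_smooth=40, seed=4)
        a = bootstrap(sparse_dataset, final_model, n_iter=3, seed=9, settings=s)
        b = bootstrap(sparse_dataset, final_model, n_iter=3, seed=9, settings=s)
        assert a.replicates.equals(b.replicates)

    def test_bootstrap_uncertainty_consistent_with_truth(
        self, final_model, sparse_dataset
    ):
        """Scaled-down bootstrap: the CL distribution brackets the truth.

        A single dataset's IQR is a ~50% interval around that dataset's own
        estimate, so the check uses a 4-SD band around the bootstrap median
        and the reported-precision rule (RSE < 50%).
        """
        res = bootstrap(
            sparse_dataset,
            final_model,
            n_iter=30,
            seed=1,
            settings=SaemSettings(n_explore=80, n_smooth=80, seed=1),
        )
        med = res.summary.loc["theta_CL", "median"]
        sd = res.summary.loc["theta_CL", "sd"]
        assert abs(med - 11.57) < 4 * sd
        assert res.summary.loc["theta_CL", "q25"] < med < res.summary.loc["theta_CL", "q75"]
        assert res.summary.loc["theta_CL", "rse_pct"] < 50.0
        assert res.n_failed == 0
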