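"""Closed-form two-compartment infusion solution against its ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from ceftriaxpk import (
    DoseRegimen,
    StructuralParams,
    conc_profile,
    hybrid_constants,
    ode_oracle,
)
from ceftriaxpk.pta import SIX_REGIMENS

MEDIANS = np.array([11.57, 43.6, 19.8, 40.94])


class TestHybridConstants:
    def test_micro_constants_from_published_medians(self, median_params):
        assert median_params.k10 == pytest.approx(11.57 / 43.6, rel=1e-12)
        assert median_params.k12 == pytest.approx(19.8 / 43.6, rel=1e-12)
        assert median_params.k21 == pytest.approx(19.8 / 40.94, rel=1e-12)

    def test_sum_and_product_identities(self, median_params):
        h = hybrid_constants(median_params)
        p = median_params
        assert h.alpha * h.beta == pytest.approx(p.k10 * p.k21, rel=1e-10)
        assert h.alpha + h.beta == pytest.approx(p.k10 + p.k12 + p.k21, rel=1e-10)
        assert h.alpha >= h.beta > 0
        assert h.coef_alpha + h.coef_beta == pytest.approx(1.0, abs=1e-12)

    def test_one_compartment_collapse(self):
        p = StructuralParams(CL=11.57, V1=43.6, Q=0.0, V2=40.94)
        h = hybrid_constants(p)
        assert h.alpha == pytest.approx(p.k10, rel=1e-12)
        assert h.beta == 0.0
        assert h.coef_alpha == 1.0

    @pytest.mark.parametrize("bad", [dict(CL=-1), dict(V1=0), dict(V2=-5), dict(Q=-0.1)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(CL=11.57, V1=43.6, Q=19.8, V2=40.94)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            StructuralParams(**kwargs)

    @hyp_settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        logf=st.tuples(*[st.floats(np.log(0.2), np.log(5.0)) for _ in range(4)])
    )
    def test_identities_hold_over_parameter_space(self, logf):
        th = MEDIANS * np.exp(np.array(logf))
        p = StructuralParams(*th)
        h = hybrid_constants(p)
        assert h.alpha * h.beta == pytest.approx(p.k10 * p.k21, rel=1e-10, abs=1e-14)
        assert h.alpha + h.beta == pytest.approx(p.k10 + p.k12 + p.k21, rel=1e-10)


class TestConcProfile:
    def test_zero_before_and_at_start(self, median_params):
        reg = DoseRegimen(dose=2000, t_inf=1, tau=12, n_doses=1)
        conc = conc_profile(median_params, reg, np.array([0.0]))
        assert conc[0] == 0.0

    def test_zero_dose_gives_zero_profile(self, median_params):
        reg = DoseRegimen(dose=0.0, t_inf=1, tau=12, n_doses=5)
        t = np.linspace(0, 60, 30)
        assert np.all(conc_profile(median_params, reg, t) == 0.0)

    def test_empty_grid(self, median_params):
        reg = DoseRegimen(dose=2000, t_inf=1, tau=12)
        assert conc_profile(median_params, reg, np.array([])).size == 0

    def test_negative_time_rejected(self, median_params):
        reg = DoseRegimen(dose=2000, t_inf=1, tau=12)
        with pytest.raises(ValueError):
            conc_profile(median_params, reg, np.array([-1.0]))

    def test_continuous_infusion_steady_state_is_rate_over_clearance(self):
        """Css = R0/CL independently of V1, Q, V2 (6 g/24 h -> 21.61 mg/L)."""
        for v1, q, v2 in [(43.6, 19.8, 40.94), (20.0, 5.0, 100.0), (80.0, 50.0, 10.0)]:
            p = StructuralParams(CL=11.57, V1=v1, Q=q, V2=v2)
            reg = DoseRegimen(dose=6000, t_inf=24, tau=24, n_doses=30)
            css = conc_profile(p, reg, np.array([700.0]))[0]
            assert css == pytest.approx(250.0 / 11.57, rel=1e-6)

    def test_linearity_in_dose(self, median_params):
        t = np.linspace(0, 60, 50)
        base = conc_profile(median_params, DoseRegimen(2000, 1, 12, 5), t)
        scaled = conc_profile(median_params, DoseRegimen(5000, 1, 12, 5), t)
        assert scaled == pytest.approx(2.5 * base, rel=1e-12)

    def test_superposition_of_shifted_single_doses(self, median_params):
        t = np.linspace(0, 60, 101)
        multi = conc_profile(median_params, DoseRegimen(2000, 1, 12, 4), t)
        total = np.zeros_like(t)
        for k in range(4):
            single = conc_profile(
                median_params, DoseRegimen(2000, 1, 12, 1), np.maximum(t - 12 * k, 0.0)
            )
            total += single
        assert multi == pytest.approx(total, rel=1e-10, abs=1e-12)

    def test_continuity_across_infusion_end(self, median_params):
        reg = DoseRegimen(dose=2000, t_inf=1, tau=12, n_doses=1)
        eps = 1e-7
        c = conc_profile(median_params, reg, np.array([1 - eps, 1.0, 1 + eps]))
        assert c[0] == pytest.approx(c[1], rel=1e-5)
        assert c[2] == pytest.approx(c[1], rel=1e-5)


class TestOdeOracleAgreement:
    def test_single_infusion_matches_ode(self, median_params):
        reg = DoseRegimen(dose=2000, t_inf=1, tau=12, n_doses=1)
        t = np.linspace(0, 24, 100)
        cf = conc_profile(median_params, reg, t)
        oo = ode_oracle(median_params, reg, t)
        mask = oo > 1e-6
        assert np.max(np.abs(cf[mask] - oo[mask]) / oo[mask]) < 1e-3

    def test_ode_zero_dose_identically_zero(self, median_params):
        reg = DoseRegimen(dose=0.0, t_inf=1, tau=12, n_doses=3)
        t = np.linspace(0, 36, 20)
        assert np.all(ode_oracle(median_params, reg, t) == 0.0)

    def test_ode_linearity(self, median_params):
        t = np.linspace(0, 40, 30)
        a = ode_oracle(median_params, DoseRegimen(2000, 1, 12, 3), t)
        b = ode_oracle(median_params, DoseRegimen(4000, 1, 12, 3), t)
        assert b == pytest.approx(2 * a, rel=1e-6, abs=1e-9)

    def test_random_parameters_all_regimens(self):
        """Closed form vs ODE within 0.1% over random log-uniform parameters."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            th = MEDIANS * np.exp(rng.uniform(np.log(0.2), np.log(5), 4))
            p = StructuralParams(*th)
            for dose, t_inf, tau in SIX_REGIMENS.values():
                reg = DoseRegimen(dose, t_inf, tau, n_doses=3)
                t = np.linspace(0, 3 * tau + 6, 60)
                cf = conc_profile(p, reg, t)
                oo = ode_oracle(p, reg, t)
                denom = np.maximum(np.abs(oo), 1e-6 * oo.max())
                assert np.max(np.abs(cf - oo) / denom) < 1e-3

    def test_degenerate_one_compartment_against_ode(self):
        p = StructuralParams(CL=11.57, V1=43.6, Q=0.0, V2=40.94)
        reg = DoseRegimen(2000, 1, 12, 4)
        t = np.linspace(0, 48, 60)
        cf = conc_profile(p, reg, t)
        oo = ode_oracle(p, reg, t)
        mask = oo > 1e-9
        assert np.max(np.abs(cf[mask] - oo[mask]) / oo[mask]) < 1e-3
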