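"""Variance-decomposition unit and oracle tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igeam.components import (
    EquilibriumCorrelations,
    RandomMatingComponents,
    components_from_variances,
    equilibrium_cge_via_cge0,
    equilibrium_decomposition,
    h2eq_from_h2f,
    random_mating_components,
    rdelta_under_phenotypic_assortment,
    sib_regression_expectation,
)

from _mc import clustered_var_se, corr_se, predicted_vy_se


class TestRandomMatingComponents:
    def test_single_variant_closed_form(self):
        rm = random_mating_components([1.0], [0.0], [0.5], sigma_eps2=0.5)
        assert rm.vg == pytest.approx(0.5)
        assert rm.ve_g == 0.0
        assert rm.cge == 0.0
        assert rm.r_dg_ig_0 == 0.0
        assert rm.vy == pytest.approx(1.0)

    def test_zero_dge_vector(self):
        rm = random_mating_components([0.0, 0.0], [1.0, -1.0], [0.3, 0.4])
        assert rm.vg == 0.0
        assert rm.cge == 0.0

    def test_sum_rule_and_correlation_bound(self):
        rng = np.random.default_rng(3)
        d, e = rng.standard_normal(50), rng.standard_normal(50)
        f = rng.uniform(0.05, 0.5, 50)
        rm = random_mating_components(d, e, f, sigma_eps2=0.2)
        het = f * (1 - f)
        assert rm.vy == pytest.approx(
            2 * np.sum(d * d * het) + 4 * np.sum(e * e * het) + 4 * np.sum(d * e * het) + 0.2
        )
        assert abs(rm.r_dg_ig_0) <= 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            random_mating_components([1.0], [1.0, 2.0], [0.5])
        with pytest.raises(ValueError, match="frequencies"):
            random_mating_components([1.0], [0.0], [1.0])
        with pytest.raises(ValueError):
            RandomMatingComponents(vg=1.0, ve_g=0.1, cge=1.0, sigma_eps2=0.0)

    @pytest.mark.parametrize(
        "r0, cge", [(0.0, 0.0), (0.5, 0.177), (1.0, 0.354)]
    )
    def test_simulation_design_cge_constants(self, r0, cge):
        # vg = 0.5, ve_g = 0.125 gives cge = r0 * sqrt(0.125)
        rm = components_from_variances(0.5, 0.125, r0)
        assert round(rm.cge, 3) == cge
        assert rm.vy == pytest.approx(1.0)


class TestEquilibriumDecomposition:
    def test_random_mating_limit(self):
        """Without AM the parents are uncorrelated (r_delta = r_eta = trans =
        0) but the within-parent DGE-IGE correlation equals the genome-wide
        effect correlation; the decomposition then reproduces the
        random-mating components exactly."""
        rm = components_from_variances(0.5, 0.125, 0.5)
        corr = EquilibriumCorrelations(0.0, 0.0, rm.r_dg_ig_0, 0.0)
        eq = equilibrium_decomposition(rm, corr)
        assert eq.vg_eq == pytest.approx(rm.vg)
        assert eq.ve_g_eq == pytest.approx(rm.ve_g)
        assert eq.cge_eq == pytest.approx(rm.cge)
        assert eq.vy_eq == pytest.approx(rm.vy)
        assert eq.h2_f(rm) == pytest.approx(eq.h2_eq)

    def test_crow_felsenstein_single_factor(self):
        rm = RandomMatingComponents(vg=0.5, ve_g=0.0, cge=0.0, sigma_eps2=0.5)
        eq = equilibrium_decomposition(rm, EquilibriumCorrelations(0.5, 0.0))
        assert eq.vg_eq == pytest.approx(1.0)
        assert eq.cge_eq == 0.0
        assert eq.h2_f(rm) == pytest.approx((1 - 0.5) * eq.h2_eq)

    def test_monotone_in_parental_correlations(self):
        rm = components_from_variances(0.5, 0.125, 0.5)
        vg_eqs = [
            equilibrium_decomposition(rm, EquilibriumCorrelations(rd, 0.0)).vg_eq
            for rd in (0.0, 0.2, 0.4, 0.6)
        ]
        assert np.all(np.diff(vg_eqs) > 0)
        ve_eqs = [
            equilibrium_decomposition(rm, EquilibriumCorrelations(0.0, re)).ve_g_eq
            for re in (0.0, 0.2, 0.4, 0.6)
        ]
        assert np.all(np.diff(ve_eqs) > 0)

    def test_degenerate_correlation_raises(self):
        rm = components_from_variances(0.5, 0.125, 0.5)
        with pytest.raises(ValueError):
            equilibrium_decomposition(rm, EquilibriumCorrelations(1.0, 0.0))

    @given(
        rd=st.floats(0.0, 0.8),
        re=st.floats(0.0, 0.8),
        t=st.floats(0.0, 0.4),
        r0=st.floats(0.1, 1.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_cge_routes_agree_on_consistent_inputs(self, rd, re, t, r0):
        """The cge-based route equals the primary decomposition whenever the
        correlations satisfy the equilibrium identity
        cis - trans = r0 * sqrt((1-rd)(1-re))."""
        c = t + r0 * math.sqrt((1 - rd) * (1 - re))
        if c > 1.0:
            return
        try:
            corr = EquilibriumCorrelations(rd, re, c, t)
        except ValueError:
            return  # jointly infeasible correlation set
        rm = components_from_variances(0.4, 0.1, r0)
        eq = equilibrium_decomposition(rm, corr)
        assert equilibrium_cge_via_cge0(rm, corr) == pytest.approx(eq.cge_eq, rel=1e-9)

    def test_cge_route_requires_nonzero_effect_correlation(self):
        rm = components_from_variances(0.5, 0.125, 0.0)
        with pytest.raises(ValueError, match="r_dg_ig_0"):
            equilibrium_cge_via_cge0(rm, EquilibriumCorrelations(0.2, 0.1, 0.1, 0.05))

    def test_correlation_matrix_must_be_psd(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            EquilibriumCorrelations(0.9, 0.9, 0.9, -0.9)
        with pytest.raises(ValueError, match="outside"):
            EquilibriumCorrelations(1.2, 0.0)


class TestPhenotypicAssortment:
    def test_classic_result_without_ige(self):
        assert rdelta_under_phenotypic_assortment(0.5, 0.5) == pytest.approx(0.25)

    def test_zero_spousal_correlation(self):
        assert rdelta_under_phenotypic_assortment(0.5, 0.0, 0.2, 0.6) == 0.0

    def test_requires_positive_vg_eq_with_covariance(self):
        with pytest.raises(ValueError):
            rdelta_under_phenotypic_assortment(0.5, 0.5, cge_eq=0.2, vg_eq=0.0)


class TestSibRegression:
    def test_no_am_no_ige(self):
        rm = RandomMatingComponents(vg=0.5, ve_g=0.0, cge=0.0, sigma_eps2=0.5)
        eq = equilibrium_decomposition(rm, EquilibriumCorrelations(0.0, 0.0))
        exp = sib_regression_expectation(rm, eq, EquilibriumCorrelations(0.0, 0.0))
        assert exp.slope == pytest.approx(0.5)
        assert exp.intercept == pytest.approx(0.0)

    def test_am_inflates_intercept_without_shared_environment(self):
        """Under AM the intercept contains r_delta*h2_eq even with no IGEs and
        independent residuals, biasing 'shared environment' upward."""
        rm = RandomMatingComponents(vg=0.5, ve_g=0.0, cge=0.0, sigma_eps2=0.5)
        corr = EquilibriumCorrelations(0.3, 0.0)
        eq = equilibrium_decomposition(rm, corr)
        exp = sib_regression_expectation(rm, eq, corr, resid_cov=0.0)
        assert exp.intercept == pytest.approx(0.3 * eq.h2_eq)
        assert exp.intercept > 0

    def test_intercept_correction_identity(self):
        rm = components_from_variances(0.5, 0.125, 0.5)
        corr = EquilibriumCorrelations(0.3, 0.2, 0.4, 0.25)
        eq = equilibrium_decomposition(rm, corr)
        exp = sib_regression_expectation(rm, eq, corr, resid_cov=0.05)
        h2f = eq.h2_f(rm)
        corrected = exp.intercept - 0.3 / (1 - 0.3) * h2f
        assert corrected == pytest.approx((eq.ve_g_eq + eq.cge_eq + 0.05) / eq.vy_eq)


class TestH2eqFromH2f:
    def test_height_rdr_and_twin_inputs(self):
        assert round(h2eq_from_h2f(0.554, 0.106 / (0.452 + 0.548 * 0.106)), 3) == 0.699
        assert round(h2eq_from_h2f(0.729, 0.106 / (0.346 + 0.654 * 0.106)), 3) == 0.979

    def test_identity_without_am(self):
        assert h2eq_from_h2f(0.5, 0.0) == 0.5

    def test_rejects_degenerate_correlation(self):
        with pytest.raises(ValueError):
            h2eq_from_h2f(0.5, 1.0)


class TestSimulatorOracles:
    """Pin the typographically ambiguous equilibrium formulas against the
    forward simulator."""

    def test_random_mating_sum_rule_empirical(self, sim_random):
        rm = sim_random.random_mating_components()
        vy_emp, se = clustered_var_se(sim_random.offspring_y)
        assert abs(rm.vy - vy_emp) < 3 * se

    def test_equilibrium_cge_matches_simulation(self, sim_am_ige):
        res = sim_am_ige
        rm = res.random_mating_components()
        corr = res.equilibrium_correlations()
        eq = equilibrium_decomposition(rm, corr)
        dge = res.offspring_dge.ravel()
        ige = np.repeat(res.offspring_parental_ige, 2)
        cge_emp = 2.0 * float(np.cov(dge, ige)[0, 1])
        # MC noise on the empirical covariance plus correlation-measurement noise
        n = res.config.n_families
        tol = 3 * (abs(eq.cge_eq) * 0.06 + corr_se(corr.r_de_cis, n) * abs(eq.cge_eq))
        assert abs(eq.cge_eq - cge_emp) < max(tol, 0.06)
        # alternative route agrees with the primary one on simulator-measured inputs
        assert equilibrium_cge_via_cge0(rm, corr) == pytest.approx(eq.cge_eq, abs=0.02)

    def test_phenotypic_assortment_prediction_no_ige(self, sim_am_noige):
        res = sim_am_noige
        corr = res.equilibrium_correlations()
        eq = equilibrium_decomposition(res.random_mating_components(), corr)
        ry = float(res.summary.iloc[-1]["r_y_realized"])
        pred = rdelta_under_phenotypic_assortment(eq.h2_eq, ry)
        assert abs(pred - corr.r_delta) < 3 * corr_se(corr.r_delta, res.config.n_families)

    def test_phenotypic_assortment_prediction_with_ige(self, sim_am_ige):
        """The (1 + cge_eq/(2 vg_eq))^2 correction is required when DGE and IGE
        components covary; the uncorrected classic prediction is visibly off."""
        res = sim_am_ige
        corr = res.equilibrium_correlations()
        eq = equilibrium_decomposition(res.random_mating_components(), corr)
        ry = float(res.summary.iloc[-1]["r_y_realized"])
        pred = rdelta_under_phenotypic_assortment(eq.h2_eq, ry, eq.cge_eq, eq.vg_eq)
        tol = 3 * corr_se(corr.r_delta, res.config.n_families)
        assert abs(pred - corr.r_delta) < max(tol, 0.02)
        classic = rdelta_under_phenotypic_assortment(eq.h2_eq, ry)
        assert abs(classic - corr.r_delta) > abs(pred - corr.r_delta)

    def test_equilibrium_vy_prediction(self, sim_am_ige):
        res = sim_am_ige
        rm = res.random_mating_components()
        corr = res.equilibrium_correlations()
        eq = equilibrium_decomposition(rm, corr)
        vy_emp, se_emp = clustered_var_se(res.offspring_y)
        se_pred = predicted_vy_se(rm, corr, res.config.n_families)
        assert abs(eq.vy_eq - vy_emp) < 3 * math.hypot(se_emp, se_pred)
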