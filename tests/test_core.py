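"""Demographic process: links, matrix, projections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seabirdipm.core import (
    BREEDING_STAGE,
    DegenerateSeriesError,
    MissingCovariateError,
    ProductivityCoefficients,
    SurvivalCoefficients,
    VitalRates,
    build_transition_matrix,
    dominant_eigenvalue,
    productivity_rate,
    project_deterministic,
    project_stochastic,
    standardize,
    survival_rates,
)


class TestStandardize:
    def test_centres_and_scales_with_sample_sd(self):
        z, mean, sd = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert mean == 2.0 and sd == 1.0

    def test_idempotent_on_standardized_input(self):
        z, *_ = standardize([-1.0, 0.0, 1.0])
        z2, mean, sd = standardize(z)
        np.testing.assert_allclose(z2, z, atol=1e-12)
        assert abs(mean) < 1e-12 and abs(sd - 1.0) < 1e-12

    def test_missing_entries_stay_flagged(self):
        x = np.array([1.0, np.nan, 2.0, 3.0, np.nan])
        z, mean, sd = standardize(x)
        assert np.isnan(z[[1, 4]]).all()
        obs = z[~np.isnan(z)]
        assert abs(obs.mean()) < 1e-12 and abs(obs.std(ddof=1) - 1.0) < 1e-12

    @pytest.mark.parametrize("bad", [[5.0, 5.0, 5.0], [7.0], []])
    def test_degenerate_inputs_raise(self, bad):
        with pytest.raises(DegenerateSeriesError):
            standardize(bad)


class TestSurvivalLink:
    def test_baseline_when_covariates_zero(self):
        c = SurvivalCoefficients(alpha_f0=-0.4, alpha_a0=2.0, alpha_1=-1.0)
        pf, pa = survival_rates(c, P=0.0, S1=0.0)
        np.testing.assert_allclose(pf, 1 / (1 + np.exp(0.4)))
        np.testing.assert_allclose(pa, 1 / (1 + np.exp(-2.0)))

    def test_indicators_switch_off_covariates(self):
        c = SurvivalCoefficients(
            alpha_f0=0.3, alpha_a0=1.0, alpha_1=5.0, alpha_2=-3.0, alpha_3=2.0,
            I1=0, I2=0, I3=0,
        )
        base = survival_rates(c, P=0.0, S1=0.0)
        for P, S1 in [(2.0, -1.0), (-3.0, 4.0)]:
            assert survival_rates(c, P=P, S1=S1) == base

    def test_hand_evaluated_fledgling_rate(self):
        c = SurvivalCoefficients(
            alpha_f0=0.0, alpha_a0=0.0, alpha_1=0.5, alpha_2=0.5, alpha_3=0.0,
            I1=1, I2=1, I3=0,
        )
        pf, _ = survival_rates(c, P=1.0, S1=123.0)
        np.testing.assert_allclose(pf, 1 / (1 + np.exp(-1.0)), atol=1e-5)
        assert round(float(pf), 5) == 0.73106

    def test_shared_term_excludes_extra_fledgling_predation_from_adults(self):
        c = SurvivalCoefficients(alpha_1=0.0, alpha_2=-2.0, I1=1, I2=1, I3=0)
        _, pa = survival_rates(c, P=1.0, S1=0.0)
        np.testing.assert_allclose(pa, 0.5)

    def test_missing_covariate_names_year(self):
        c = SurvivalCoefficients()
        with pytest.raises(MissingCovariateError, match="1994"):
            survival_rates(c, P=np.nan, S1=0.0, year=1994)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a1=st.floats(-3.0, -0.01),
        p1=st.floats(-3.0, 3.0),
        dp=st.floats(0.0, 3.0),
        a0=st.floats(-2.0, 3.0),
    )
    def test_negative_predation_effect_is_monotone(self, a1, p1, dp, a0):
        """With a negative shared coefficient, more predation never
        increases adult survival."""
        c = SurvivalCoefficients(alpha_a0=a0, alpha_1=a1, I1=1, I2=0, I3=0)
        _, lo = survival_rates(c, P=p1 + dp, S1=0.0)
        _, hi = survival_rates(c, P=p1, S1=0.0)
        assert lo <= hi + 1e-12


class TestProductivityLink:
    def test_baseline_and_switch_off(self):
        c = ProductivityCoefficients(beta_0=0.2, beta=np.arange(10.0), J=np.zeros(10, int))
        x = np.random.default_rng(0).normal(size=10)
        np.testing.assert_allclose(
            productivity_rate(c, x), 1 / (1 + np.exp(-0.2))
        )

    def test_hand_evaluated_density_dependence(self):
        J = np.zeros(10, int)
        J[9] = 1
        beta = np.zeros(10)
        beta[9] = -1.0
        c = ProductivityCoefficients(beta_0=0.0, beta=beta, J=J)
        x = np.zeros(10)
        x[9] = 1.0  # standardized breeder count one SD above its mean
        b = productivity_rate(c, x)
        assert round(float(b), 5) == 0.26894

    def test_vectorised_over_years(self):
        c = ProductivityCoefficients(beta_0=0.1)
        X = np.random.default_rng(1).normal(size=(7, 10))
        b = productivity_rate(c, X)
        assert b.shape == (7,)
        np.testing.assert_allclose(b[0], productivity_rate(c, X[0]))


class TestTransitionMatrix:
    def test_structure_at_unit_survival(self):
        R = build_transition_matrix(VitalRates(phi_f=1 - 1e-12, phi_a=1 - 1e-12, b=1 - 1e-12))
        np.testing.assert_allclose(R[0, 5], 0.5)
        np.testing.assert_allclose(np.diag(R, -1), np.ones(5))
        np.testing.assert_allclose(R[5, 5], 1.0)
        assert np.count_nonzero(R) == 7

    def test_zero_adult_survival_kills_projection(self):
        R = build_transition_matrix(VitalRates(phi_f=0.5, phi_a=1e-300, b=0.5))
        np.testing.assert_allclose(R, 0.0, atol=1e-290)

    def test_dominant_eigenvalue_two_independent_routes(self):
        """Power iteration agrees with the characteristic-polynomial root."""
        v = VitalRates(phi_f=0.37, phi_a=0.87, b=0.51)
        R = build_transition_matrix(v)
        # route 1: power iteration
        x = np.ones(6)
        for _ in range(2000):
            x = R @ x
            x /= np.linalg.norm(x)
        lam_power = float(x @ R @ x)
        # route 2: closed-form characteristic polynomial
        F = v.phi_a * (v.b / 2) * v.phi_f
        roots = np.roots([1.0, -v.phi_a, 0, 0, 0, 0, -F * v.phi_a**5])
        lam_poly = float(np.max(roots[np.abs(roots.imag) < 1e-12].real))
        assert abs(lam_power - lam_poly) < 1e-10
        assert abs(dominant_eigenvalue(R) - lam_poly) < 1e-10

    def test_long_run_growth_converges_to_dominant_eigenvalue(self):
        v = VitalRates(phi_f=0.4, phi_a=0.9, b=0.5)
        R = build_transition_matrix(v)
        lam = dominant_eigenvalue(R)
        state = np.array([0.0, 0, 0, 0, 0, 100.0])
        for _ in range(500):
            prev = state.sum()
            state = R @ state
            growth = state.sum() / prev
        assert abs(growth - lam) / lam < 1e-6


class TestProjection:
    def test_deterministic_hand_product(self):
        R = build_transition_matrix(VitalRates(phi_f=0.4, phi_a=0.9, b=0.5))
        out = project_deterministic([0, 0, 0, 0, 0, 100], R)
        np.testing.assert_allclose(out[0], 9.0)
        np.testing.assert_allclose(out[5], 90.0)

    def test_conservation_without_breeding_or_mortality(self):
        v = VitalRates(phi_f=0.5, phi_a=1 - 1e-12, b=1e-12)
        R = build_transition_matrix(v)
        state = np.array([3.0, 1, 4, 1, 5, 9])
        total = state.sum()
        for _ in range(5):
            state = project_deterministic(state, R)
            np.testing.assert_allclose(state.sum(), total, rtol=1e-9)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            project_deterministic([1.0, 2.0], np.eye(6))

    def test_stochastic_zero_state_stays_zero(self, rng):
        v = VitalRates(phi_f=0.4, phi_a=0.9, b=0.5)
        out = project_stochastic(np.zeros(6, int), v, rng)
        assert (out == 0).all()

    def test_stochastic_forced_structure(self, rng):
        """At certain survival, next-year recruits are Binomial(n6, b/2)."""
        v = VitalRates(phi_f=1 - 1e-12, phi_a=1 - 1e-12, b=1 - 1e-12)
        state = np.array([0, 0, 0, 0, 0, 100])
        draws = np.array([project_stochastic(state, v, rng)[0] for _ in range(800)])
        assert draws.min() >= 0 and draws.max() <= 100
        assert abs(draws.mean() - 50.0) < 3 * 5.0 / np.sqrt(800)

    def test_stochastic_requires_integers(self, rng):
        with pytest.raises(ValueError, match="integer"):
            project_stochastic(np.full(6, 1.5), VitalRates(0.4, 0.9, 0.5), rng)

    def test_stochastic_mean_matches_deterministic(self, rng):
        """Monte-Carlo oracle: the expectation of every stochastic
        component equals the deterministic projection (3 SE)."""
        v = VitalRates(phi_f=0.4, phi_a=0.87, b=0.5)
        state = np.array([10, 10, 10, 10, 10, 200])
        R = build_transition_matrix(v)
        expect = project_deterministic(state, R)
        n = 4000
        sims = np.array([project_stochastic(state, v, rng) for _ in range(n)])
        se = sims.std(axis=0, ddof=1) / np.sqrt(n)
        assert (np.abs(sims.mean(axis=0) - expect) <= 3 * se + 1e-9).all()
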