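"""Synthetic-data generator: covariate processes, truth, observations."""

import numpy as np
import pytest

from seabirdipm.core import BREEDING_STAGE, VitalRates, build_transition_matrix, dominant_eigenvalue
from seabirdipm.simulate import (
    ScenarioConfig,
    generate_covariates,
    generate_dataset,
    generate_observations,
    generate_truth,
    scenario_paper_like,
    scenario_strong_survival_predation,
)
from seabirdipm.trajectory import fit_broken_stick
from dataclasses import replace

from seabirdipm.core import ProductivityCoefficients, SurvivalCoefficients


def _lag1_autocorr(x):
    x = x - x.mean()
    return float((x[:-1] * x[1:]).sum() / (x**2).sum())


class TestCovariateGeneration:
    def test_zero_ar_coefficient_gives_white_noise(self):
        cfg = replace(ScenarioConfig(n_years=400), ar_coef_ssta=0.0)
        cov = generate_covariates(cfg, seed=5)
        r = _lag1_autocorr(cov["S"][~np.isnan(cov["S"])])
        assert abs(r) < 3 / np.sqrt(400)

    def test_ar_coefficient_recovered_in_large_sample(self):
        cfg = replace(ScenarioConfig(n_years=2000), ar_coef_ssta=0.7)
        cov = generate_covariates(cfg, seed=6)
        r = _lag1_autocorr(cov["S"])
        assert abs(r - 0.7) < 0.05

    def test_fixed_seed_is_bit_reproducible(self):
        cfg = ScenarioConfig()
        a = generate_covariates(cfg, seed=3)
        b = generate_covariates(cfg, seed=3)
        for col in ("P", "S", "A", "D"):
            np.testing.assert_array_equal(a[col], b[col])

    def test_missingness_pattern_applied_after_standardization(self):
        cov = generate_covariates(ScenarioConfig(), seed=1)
        assert np.isnan(cov["P"][:16]).all() and (~np.isnan(cov["P"][16:])).all()
        assert np.isnan(cov["A"][:4]).all() and (~np.isnan(cov["A"][4:])).all()
        obs = cov["P"][16:]
        assert abs(obs.mean()) < 1e-8 and abs(obs.std(ddof=1) - 1) < 1e-8


class TestTruthGeneration:
    def _null_config(self, **kw):
        return replace(
            ScenarioConfig(),
            survival=SurvivalCoefficients(
                alpha_f0=np.log(0.4 / 0.6), alpha_a0=np.log(0.9 / 0.1),
                alpha_1=0.0, alpha_2=0.0, alpha_3=0.0, I1=0, I2=0, I3=0,
            ),
            productivity=ProductivityCoefficients(
                beta_0=0.0, beta=np.zeros(10), J=np.zeros(10, int)
            ),
            **kw,
        )

    def test_zero_initial_population_stays_zero(self):
        cfg = self._null_config(initial_females=0)
        cov = generate_covariates(cfg, seed=2)
        N, CF, vital = generate_truth(cfg, cov, seed=2)
        assert (N == 0).all() and (CF == 0).all()

    def test_long_run_growth_matches_dominant_eigenvalue(self):
        """Covariate-free truth grows at the matrix's dominant eigenvalue
        (Monte-Carlo over replicates)."""
        cfg = self._null_config(initial_females=5000, n_years=20)
        cov = generate_covariates(cfg, seed=8)
        lam = dominant_eigenvalue(
            build_transition_matrix(VitalRates(phi_f=0.4, phi_a=0.9, b=0.5))
        )
        growths = []
        for rep in range(120):
            N, _, _ = generate_truth(cfg, cov, seed=1000 + rep)
            total0 = N[5].sum()
            total1 = N[-1].sum()
            growths.append((total1 / total0) ** (1 / (cfg.n_years - 6)))
        mean_growth = np.mean(growths)
        se = np.std(growths, ddof=1) / np.sqrt(len(growths))
        assert abs(mean_growth - lam) < max(3 * se, 0.004)

    def test_density_dependence_reduces_variance(self):
        """Negative feedback through the auto-covariate shrinks the spread
        of the breeder series relative to the density-independent twin."""
        base = self._null_config(initial_females=1500, n_years=40)
        J = np.zeros(10, int)
        J[9] = 1
        beta = np.zeros(10)
        beta[9] = -0.8
        dd = replace(
            base,
            productivity=ProductivityCoefficients(beta_0=0.0, beta=beta, J=J),
        )
        cov = generate_covariates(base, seed=4)
        spread_dd, spread_di = [], []
        for rep in range(25):
            N_dd, _, _ = generate_truth(dd, cov, seed=500 + rep)
            N_di, _, _ = generate_truth(base, cov, seed=500 + rep)
            spread_dd.append(np.std(np.log(N_dd[:, BREEDING_STAGE] + 1)))
            spread_di.append(np.std(np.log(N_di[:, BREEDING_STAGE] + 1)))
        assert np.mean(spread_dd) < np.mean(spread_di)


class TestObservations:
    def test_zero_variance_observations_equal_latents(self):
        cfg = replace(ScenarioConfig(), s2_counts=1e-18)
        ds_cov = generate_covariates(cfg, seed=9)
        N, CF, vital = generate_truth(cfg, ds_cov, seed=9)
        counts, _ = generate_observations(cfg, N, CF, vital, seed=9)
        np.testing.assert_allclose(counts["females"], N[:, BREEDING_STAGE], atol=1e-6)
        np.testing.assert_allclose(counts["chicks_f"], CF, atol=1e-6)

    def test_empty_survival_window_gives_empty_file(self):
        cfg = replace(ScenarioConfig(), survival_window=0)
        cov = generate_covariates(cfg, seed=10)
        N, CF, vital = generate_truth(cfg, cov, seed=10)
        counts, survival = generate_observations(cfg, N, CF, vital, seed=10)
        assert survival.empty
        assert len(counts) == cfg.n_years

    def test_observation_mean_is_unbiased(self):
        """Replicated observation sets centre on the latent values (3 SE)."""
        cfg = ScenarioConfig()
        cov = generate_covariates(cfg, seed=11)
        N, CF, vital = generate_truth(cfg, cov, seed=11)
        n_rep = 400
        sums = np.zeros(cfg.n_years)
        for rep in range(n_rep):
            counts, _ = generate_observations(cfg, N, CF, vital, seed=2000 + rep)
            sums += counts["females"].to_numpy()
        mean_obs = sums / n_rep
        se = np.sqrt(cfg.s2_counts / n_rep)
        # truncation at zero is negligible at these population sizes
        assert (np.abs(mean_obs - N[:, BREEDING_STAGE]) < 4 * se).all()

    def test_survival_cis_bracket_estimates(self):
        ds = generate_dataset(ScenarioConfig(), seed=12)
        s = ds.survival
        assert ((s["ci_low"] < s["estimate"]) & (s["estimate"] < s["ci_high"])).all()
        assert set(s["age_class"]) == {"fledgling", "older"}
        assert len(s) == 2 * ds.config.survival_window


class TestPaperLikeScenario:
    def test_fixture_is_deterministic(self):
        a = generate_dataset(scenario_paper_like())
        b = generate_dataset(scenario_paper_like())
        np.testing.assert_array_equal(a.N, b.N)
        np.testing.assert_array_equal(
            a.counts["females"].to_numpy(), b.counts["females"].to_numpy()
        )

    def test_declines_then_flattens(self, paperlike_dataset):
        ds = paperlike_dataset
        fit = fit_broken_stick(ds.years, np.maximum(ds.counts["females"], 1.0))
        assert fit.rate_pre < -4.0  # steep early decline
        assert fit.rate_post > fit.rate_pre + 3.0  # later flattening
        assert 1995 <= fit.breakpoint <= 2007

    def test_missingness_mirrors_data_availability(self, paperlike_dataset):
        cov = paperlike_dataset.cov
        years = paperlike_dataset.years
        # predation observed only from the 2001 analogue onwards
        assert (years[~np.isnan(cov["P"])] >= 2001).all()
        assert (years[~np.isnan(cov["A"])] >= 1989).all()
        # survival window: final 8 seasons
        surv_years = paperlike_dataset.survival["year"].unique()
        assert len(surv_years) == 8 and surv_years.min() == years[-8]

    def test_strong_predation_scenario_is_survival_only(self):
        cfg = scenario_strong_survival_predation()
        assert cfg.survival.alpha_1 <= -0.5
        assert cfg.survival.I2 == 0 and cfg.survival.I3 == 0
        assert (cfg.productivity.J == 0).all()
        ds = generate_dataset(cfg)
        assert (ds.N[:, BREEDING_STAGE] > 0).all()
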