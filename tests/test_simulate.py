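"""Synthetic-cohort generator: growth-factor and trajectory laws, Likert
discretization, MAR missingness, determinism, and moment agreement."""

import numpy as np
import pandas as pd
import pytest

import growthsem as gs
from growthsem.simulate import (
    GrowthParams,
    LikertItemSpec,
    LikertSpec,
    MissingnessSpec,
    StratumConfig,
    default_config,
    default_params,
    discretize_to_likert,
    factor_moments,
    implied_observed_moments,
    impose_mar_missingness,
    simulate_growth_factors,
    simulate_parallel_cohort,
    simulate_stratum,
    simulate_trajectories,
)
from growthsem import study

LOADINGS = np.vstack([np.ones(7), np.arange(7.0)])


class TestGrowthFactors:
    def test_degenerate_psi_gives_exact_means(self, rng):
        gp = GrowthParams(nu=[2.0, -0.5], Psi=np.zeros((2, 2)), theta=np.ones(7))
        eta = simulate_growth_factors(gp, None, 50, rng)
        assert np.allclose(eta, [2.0, -0.5])

    def test_slope_mean_recovered_large_n(self, rng):
        # generating slope mean 0.18 (normal-male BMI growth rate)
        psi = np.array([[9.0, 0.09], [0.09, 0.09]])
        gp = GrowthParams(nu=[23.46, 0.18], Psi=psi, theta=np.ones(7))
        eta = simulate_growth_factors(gp, None, 200_000, rng)
        se = np.sqrt(psi[1, 1] / 200_000)
        assert abs(eta[:, 1].mean() - 0.18) < 3 * se
        # intercept-slope covariance matches the generating Psi01
        c = np.cov(eta, rowvar=False)[0, 1]
        assert abs(c - 0.09) < 0.01

    def test_covariate_effects_shift_means(self, rng):
        gamma = np.array([[0.5], [0.1]])
        gp = GrowthParams(nu=[0.0, 0.0], Psi=np.zeros((2, 2)), theta=np.ones(7),
                          Gamma=gamma)
        x = np.array([[1.0], [2.0]])
        eta = simulate_growth_factors(gp, x, 2, rng)
        assert np.allclose(eta, [[0.5, 0.1], [1.0, 0.2]])

    def test_invalid_psi_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(nu=[0, 0], Psi=[[1.0, 2.0], [2.0, 1.0]], theta=np.ones(7))


class TestTrajectories:
    def test_noise_free_is_exactly_linear(self, rng):
        eta = np.array([[23.46, 0.18]])
        y = simulate_trajectories(eta, LOADINGS, np.zeros(7), rng)
        assert np.allclose(y[0], 23.46 + 0.18 * np.arange(7))
        assert y[0, 6] == pytest.approx(24.54)  # 23.46 + 6 * 0.18

    def test_wave_variance_matches_closed_form(self, rng):
        psi = np.array([[4.0, 0.2], [0.2, 0.25]])
        theta = np.linspace(0.5, 1.5, 7)
        eta = rng.multivariate_normal([0, 0], psi, 100_000)
        y = simulate_trajectories(eta, LOADINGS, theta, rng)
        for t in range(7):
            lam = LOADINGS[:, t]
            expect = lam @ psi @ lam + theta[t]
            assert y[:, t].var() == pytest.approx(expect, rel=0.03)

    def test_negative_theta_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_trajectories(np.zeros((2, 2)), LOADINGS, -np.ones(7), rng)


class TestLikert:
    ITEMS = [LikertItemSpec("a", 8, first_level=0), LikertItemSpec("b", 6),
             LikertItemSpec("c", 4)]

    def test_noise_free_is_monotone_in_score(self, rng):
        score = rng.normal(size=2000)
        items = discretize_to_likert(score, self.ITEMS, 0.0, rng)
        order = np.argsort(score)
        for j in range(3):
            diffs = np.diff(items[order, j])
            assert (diffs >= 0).all()

    def test_marginals_respect_ranges(self, rng):
        score = rng.normal(size=5000)
        items = discretize_to_likert(score, self.ITEMS, 0.4, rng)
        assert items[:, 0].min() >= 0 and items[:, 0].max() <= 7
        assert items[:, 1].min() >= 1 and items[:, 1].max() <= 6
        assert items[:, 2].min() >= 1 and items[:, 2].max() <= 4

    def test_invalid_noise_share_rejected(self, rng):
        with pytest.raises(ValueError):
            discretize_to_likert(rng.normal(size=10), self.ITEMS, 1.0, rng)

    def test_thresholds_must_increase(self, rng):
        bad = [LikertItemSpec("a", 3, thresholds=[0.5, 0.5])]
        with pytest.raises(ValueError):
            discretize_to_likert(rng.normal(size=10), bad, 0.0, rng)


class TestMissingness:
    def _panel(self, n=300, seed=4):
        cfg = default_config(n_per_stratum=None, seed=seed, missingness=None)
        cfg.strata = cfg.strata[:1]
        cfg.strata[0].n = n
        cfg.missingness = None
        return simulate_parallel_cohort(cfg)

    def test_zero_rates_are_identity(self, rng):
        panel = self._panel()
        out = impose_mar_missingness(panel, MissingnessSpec(0.0, 0.0), rng)
        pd.testing.assert_frame_equal(out.data, panel.data)

    def test_total_intermittency_leaves_one_valid_wave(self, rng):
        panel = self._panel()
        out = impose_mar_missingness(panel, MissingnessSpec(0.0, 1.0), rng)
        assert (out.valid_wave_counts() == 1).all()

    def test_original_panel_unmodified(self, rng):
        panel = self._panel()
        before = panel.data.copy()
        impose_mar_missingness(panel, MissingnessSpec(0.5, 0.5), rng)
        pd.testing.assert_frame_equal(panel.data, before)

    def test_logistic_age_dependence(self, rng):
        # empirical per-wave missingness by age group matches the logistic curve
        from scipy.special import expit, logit

        panel = self._panel(n=4000)
        spec = MissingnessSpec(0.0, 0.15, age_coef=0.8, smoking_coef=0.0)
        out = impose_mar_missingness(panel, spec, rng)
        base = out.baseline()
        miss = out.data.pivot_table(
            index="subject_id", columns="wave", values="bmi", aggfunc="first",
            dropna=False,
        ).isna()
        age = base.set_index("subject_id").loc[miss.index, "age"]
        for lo, hi in [(20, 38), (38, 46), (46, 75)]:
            grp = (age >= lo) & (age < hi)
            if grp.sum() < 200:
                continue
            obs_rate = miss.loc[grp.values, range(1, 7)].to_numpy().mean()
            pred = expit(
                logit(0.15) + 0.8 * (age[grp] - spec.age_center) / spec.age_scale
            ).mean()
            assert obs_rate == pytest.approx(pred, abs=3 * np.sqrt(0.15 * 0.85 / (grp.sum() * 6)) + 0.01)


class TestCohort:
    def test_same_seed_reproducible_different_seed_not(self):
        cfg1 = default_config(n_per_stratum=40, seed=9)
        cfg2 = default_config(n_per_stratum=40, seed=9)
        cfg3 = default_config(n_per_stratum=40, seed=10)
        p1 = simulate_parallel_cohort(cfg1)
        p2 = simulate_parallel_cohort(cfg2)
        p3 = simulate_parallel_cohort(cfg3)
        pd.testing.assert_frame_equal(p1.data, p2.data)
        assert not p1.data.equals(p3.data)

    def test_null_paths_decouple_bmi_from_behaviors(self):
        pp = default_params("male", "normal", null_paths=True)
        scfg = StratumConfig("male", "normal", 20_000, pp,
                             study.STRATA[("male", "normal")].covariates)
        df = simulate_stratum(scfg, LikertSpec(), np.random.default_rng(2))
        w0 = df[df.wave == 0]
        for col in ("pa_score", "hdb_score"):
            r = np.corrcoef(w0["bmi"], w0[col])[0, 1]
            assert abs(r) < 3.5 / np.sqrt(len(w0))

    def test_sample_moments_match_implied(self):
        pp = default_params("female", "overweight")
        scfg = StratumConfig("female", "overweight", 50_000, pp,
                             study.STRATA[("female", "overweight")].covariates)
        df = simulate_stratum(scfg, LikertSpec(), np.random.default_rng(3))
        Sigma, mu = implied_observed_moments(pp)
        wide = np.column_stack([
            df.pivot(index="subject_id", columns="wave", values=v).to_numpy()
            for v in ("bmi", "pa_score", "hdb_score")
        ])
        emp_mu = wide.mean(axis=0)
        emp_Sigma = np.cov(wide, rowvar=False)
        assert np.max(np.abs(emp_mu - mu)) < 0.06
        assert np.allclose(emp_Sigma, Sigma, atol=0.06, rtol=0.02)

    def test_marginal_bmi_factor_means_hit_reference(self):
        # the structural intercept backs out the path contribution
        pp = default_params("female", "obese")
        mean, cov, nu_star = factor_moments(pp)
        ref = study.STRATA[("female", "obese")].bmi
        assert mean[0] == pytest.approx(ref.intercept)
        assert mean[1] == pytest.approx(ref.slope)
        assert not np.allclose(nu_star, mean[:2])  # paths are nonzero here

    def test_non_positive_definite_rejected_before_sampling(self):
        pp = default_params("male", "normal")
        pp.bmi.theta = np.zeros(7)
        pp.pa.theta = np.zeros(7)
        pp.hdb.theta = np.zeros(7)
        pp.bmi.Psi = np.zeros((2, 2))
        pp.predictor_factor_cov = np.zeros((4, 4))
        with pytest.raises(np.linalg.LinAlgError):
            implied_observed_moments(pp)
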