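"""RAM engine: implied-moment closed forms, ML/FIML likelihood identities,
analytic score correctness, saturated EM, and fit behavior."""

import numpy as np
import pandas as pd
import pytest

from growthsem.growth import GrowthSpec, build_lgcm, fit_model, start_values
from growthsem.ram import (
    _profile_covariate_moments,
    _suffstats,
    fiml_loglik,
    fit_ram,
    independence_fit,
    loglik_and_score,
    ml_discrepancy,
    ml_loglik,
    saturated_loglik_complete,
    saturated_mvn_em,
)

LN2PI = np.log(2 * np.pi)


def linear_lgcm_closed_form(nu, psi, theta, T=7):
    """Hand-derived implied moments of the linear growth model:
    mu_t = nu0 + t nu1; Cov(y_t, y_s) = psi00 + (t+s) psi01 + ts psi11
    + theta_t [t == s]."""
    t = np.arange(T, dtype=float)
    mu = nu[0] + t * nu[1]
    Sigma = (
        psi[0, 0]
        + np.add.outer(t, t) * psi[0, 1]
        + np.outer(t, t) * psi[1, 1]
        + np.diag(theta)
    )
    return Sigma, mu


class TestImpliedMoments:
    def test_linear_model_matches_closed_form(self, rng):
        spec = GrowthSpec()
        model = build_lgcm(spec)
        for _ in range(20):
            nu = rng.normal(size=2)
            a = rng.normal(size=(2, 2))
            psi = a @ a.T + 0.1 * np.eye(2)
            theta = rng.uniform(0.1, 2.0, 7)
            values = {"nu_intercept": nu[0], "nu_slope": nu[1],
                      "psi_intercept": psi[0, 0], "psi_slope": psi[1, 1],
                      "psi_intercept_slope": psi[0, 1]}
            values.update({f"theta_y{t}": theta[t] for t in range(7)})
            model.set_values(values)
            Sigma, mu = model.implied_moments()
            S_cf, mu_cf = linear_lgcm_closed_form(nu, psi, theta)
            assert np.allclose(Sigma, S_cf, atol=1e-10)
            assert np.allclose(mu, mu_cf, atol=1e-10)

    def test_intercept_only_closed_form(self, rng):
        # Var(y_t) = psi00 + theta_t, Cov(y_t, y_s) = psi00
        from growthsem.ram import RamModel

        model = RamModel([f"y{t}" for t in range(4)], ["intercept"])
        for t in range(4):
            model.set_fixed("A", f"y{t}", "intercept", 1.0)
        model.add_param("nu", "M", "intercept", None, 1.5, "mean")
        model.add_param("psi", "S", "intercept", "intercept", 2.0, "variance")
        for t in range(4):
            model.add_param(f"th{t}", "S", f"y{t}", f"y{t}", 0.3 + 0.1 * t, "variance")
        Sigma, mu = model.implied_moments()
        assert np.allclose(mu, 1.5)
        assert np.allclose(Sigma - np.diag([0.3, 0.4, 0.5, 0.6]), 2.0)

    def test_simulation_agreement(self, rng):
        spec = GrowthSpec()
        model = build_lgcm(spec)
        psi = np.array([[4.0, 0.3], [0.3, 0.2]])
        values = {"nu_intercept": 1.0, "nu_slope": 0.5,
                  "psi_intercept": 4.0, "psi_slope": 0.2,
                  "psi_intercept_slope": 0.3}
        values.update({f"theta_y{t}": 1.0 for t in range(7)})
        model.set_values(values)
        Sigma, mu = model.implied_moments()
        eta = rng.multivariate_normal([1.0, 0.5], psi, 300_000)
        Y = eta @ spec.loadings + rng.normal(0, 1, (300_000, 7))
        assert np.allclose(Y.mean(0), mu, atol=0.02)
        assert np.allclose(np.cov(Y, rowvar=False), Sigma, atol=0.06)


class TestMlDiscrepancy:
    def test_zero_at_saturation(self, rng):
        a = rng.normal(size=(5, 5))
        S = a @ a.T + np.eye(5)
        ybar = rng.normal(size=5)
        assert ml_discrepancy(S, ybar, S, ybar) == pytest.approx(0.0, abs=1e-12)

    def test_univariate_hand_value(self):
        # p=1, S=2, Sigma=1: ln 1 - ln 2 + 2 - 1 = 1 - ln 2
        f = ml_discrepancy(np.array([[2.0]]), np.zeros(1), np.array([[1.0]]), np.zeros(1))
        assert f == pytest.approx(1 - np.log(2), abs=1e-12)

    def test_permutation_invariance(self, rng):
        a = rng.normal(size=(4, 4))
        S = a @ a.T + np.eye(4)
        b = rng.normal(size=(4, 4))
        Sigma = b @ b.T + 2 * np.eye(4)
        ybar, mu = rng.normal(size=4), rng.normal(size=4)
        perm = rng.permutation(4)
        f1 = ml_discrepancy(S, ybar, Sigma, mu)
        f2 = ml_discrepancy(S[np.ix_(perm, perm)], ybar[perm],
                            Sigma[np.ix_(perm, perm)], mu[perm])
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(20):
            a = rng.normal(size=(3, 3))
            S = a @ a.T + np.eye(3)
            b = rng.normal(size=(3, 3))
            Sigma = b @ b.T + np.eye(3)
            assert ml_discrepancy(S, np.zeros(3), Sigma, rng.normal(size=3)) >= 0


class TestFimlLoglik:
    def test_complete_data_equals_ml_identity(self, rng):
        Y = rng.normal(size=(80, 5))
        S = np.cov(Y, rowvar=False, ddof=0)
        ybar = Y.mean(0)
        a = rng.normal(size=(5, 5))
        Sigma = a @ a.T + np.eye(5)
        mu = rng.normal(size=5)
        # casewise sum vs sufficient-statistic formula: two independent routes
        assert fiml_loglik(Y, Sigma, mu) == pytest.approx(
            ml_loglik(S, ybar, 80, Sigma, mu), rel=1e-10)
        # and at saturation the closed form applies
        assert fiml_loglik(Y, S, ybar) == pytest.approx(
            saturated_loglik_complete(S, 80), rel=1e-10)

    def test_single_standard_normal_observation(self):
        Y = np.array([[0.0]])
        ll = fiml_loglik(Y, np.array([[1.0]]), np.zeros(1))
        assert ll == pytest.approx(-0.5 * LN2PI, abs=1e-12)

    def test_marginalization_consistency(self, rng):
        # a completely-missing variable contributes nothing
        Y = rng.normal(size=(30, 3))
        Yx = np.column_stack([Y, np.full(30, np.nan)])
        a = rng.normal(size=(4, 4))
        Sigma = a @ a.T + np.eye(4)
        mu = rng.normal(size=4)
        assert fiml_loglik(Yx, Sigma, mu) == pytest.approx(
            fiml_loglik(Y, Sigma[:3, :3], mu[:3]), rel=1e-12)

    def test_all_missing_rows_skipped_with_warning(self):
        Y = np.array([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.warns(UserWarning, match="skipped 1 rows"):
            ll, skipped = fiml_loglik(Y, np.eye(2), np.zeros(2), return_skipped=True)
        assert skipped == 1


class TestScore:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        spec = GrowthSpec()
        model = build_lgcm(spec, ("c1", "c2"))
        n = 150
        eta = rng.multivariate_normal([20, 0.2], [[4, 0.1], [0.1, 0.04]], n)
        x = rng.normal(size=(n, 2))
        Y = eta @ spec.loadings + rng.normal(0, 1, (n, 7))
        Y[rng.random((n, 7)) < 0.25] = np.nan
        df = pd.DataFrame(Y, columns=[f"y{t}" for t in range(7)])
        df["c1"], df["c2"] = x[:, 0], x[:, 1]
        _profile_covariate_moments(model, df)
        model.set_values(start_values(model, spec, df))
        stats = _suffstats(df[model.obs_names].to_numpy(float))
        w = model.working_start() + 0.03
        _, g = loglik_and_score(model, w, stats)
        h = 1e-6
        for i in range(0, len(w), 5):
            e = np.zeros_like(w)
            e[i] = h
            lp, _ = loglik_and_score(model, w + e, stats)
            lm, _ = loglik_and_score(model, w - e, stats)
            assert g[i] == pytest.approx((lp - lm) / (2 * h), rel=1e-4, abs=1e-6)


class TestSaturatedEm:
    def test_complete_data_closed_form(self, rng):
        Y = rng.normal(size=(60, 4))
        mu, Sigma, ll = saturated_mvn_em(Y)
        assert np.allclose(mu, Y.mean(0), atol=1e-6)
        assert np.allclose(Sigma, np.cov(Y, rowvar=False, ddof=0), atol=1e-5)
        assert ll == pytest.approx(
            saturated_loglik_complete(np.cov(Y, rowvar=False, ddof=0), 60), rel=1e-8)

    def test_em_increases_loglik_over_naive_start(self, rng):
        Y = rng.normal(size=(200, 4))
        Y[rng.random((200, 4)) < 0.3] = np.nan
        mu, Sigma, ll = saturated_mvn_em(Y)
        naive = fiml_loglik(Y, np.diag(np.nanvar(Y, axis=0)), np.nanmean(Y, axis=0))
        assert ll >= naive

    def test_independence_fit_closed_form(self, rng):
        Y = rng.normal(size=(50, 3))
        ll, k = independence_fit(Y)
        expect = sum(
            -0.5 * 50 * (LN2PI + np.log(Y[:, j].var()) + 1) for j in range(3)
        )
        assert ll == pytest.approx(expect, rel=1e-10)
        assert k == 6


class TestFit:
    def test_parameter_recovery_within_sampling_error(self, linear_lgcm_data):
        df, truth = linear_lgcm_data
        spec = GrowthSpec()
        model = build_lgcm(spec)
        res = fit_model(model, df, estimator="ml", spec=spec)
        assert res.converged
        assert res.df == 23
        checks = {
            "nu_intercept": truth["nu"][0], "nu_slope": truth["nu"][1],
            "psi_intercept": truth["psi"][0, 0], "psi_slope": truth["psi"][1, 1],
            "psi_intercept_slope": truth["psi"][0, 1],
        }
        for name, val in checks.items():
            assert abs(res.estimates[name] - val) < 4 * res.se[name], name

    def test_multistart_stability(self, linear_lgcm_data, rng):
        df, _ = linear_lgcm_data
        spec = GrowthSpec()
        logliks = []
        base = start_values(build_lgcm(spec), spec, df)
        for _ in range(5):
            model = build_lgcm(spec)
            jitter = {}
            for k, v in base.items():
                if k.startswith("nu"):
                    jitter[k] = v + 0.5 * rng.normal()
                elif k == "psi_intercept_slope":
                    jitter[k] = v + 0.05 * rng.normal()
                else:  # variances: jitter on the log scale
                    jitter[k] = v * np.exp(0.3 * rng.normal())
            res = fit_ram(model, df, estimator="ml", start=jitter,
                          compute_se=False)
            logliks.append(res.loglik)
        assert np.ptp(logliks) < 1e-6 * (1 + abs(logliks[0]))

    def test_fiml_equals_ml_on_complete_data(self, linear_lgcm_data):
        df, _ = linear_lgcm_data
        spec = GrowthSpec()
        r_ml = fit_model(build_lgcm(spec), df, estimator="ml", spec=spec,
                         compute_se=False)
        r_fi = fit_model(build_lgcm(spec), df, estimator="fiml", spec=spec,
                         compute_se=False)
        assert r_fi.loglik == pytest.approx(r_ml.loglik, rel=1e-9)
        for k in r_ml.model.free_names:
            assert r_fi.estimates[k] == pytest.approx(
                r_ml.estimates[k], rel=1e-6, abs=1e-8)

    def test_fiml_uses_partial_rows(self, linear_lgcm_data, rng):
        df, truth = linear_lgcm_data
        df = df.copy()
        arr = df.to_numpy()
        arr[rng.random(arr.shape) < 0.25] = np.nan
        dfm = pd.DataFrame(arr, columns=df.columns)
        spec = GrowthSpec()
        res = fit_model(build_lgcm(spec), dfm, estimator="fiml", spec=spec)
        assert res.converged
        assert abs(res.estimates["nu_slope"] - truth["nu"][1]) < 4 * res.se["nu_slope"]

    def test_nonconvergence_is_reported_not_raised(self, linear_lgcm_data):
        df, _ = linear_lgcm_data
        spec = GrowthSpec()
        model = build_lgcm(spec)
        res = fit_ram(model, df.iloc[:40], estimator="ml", compute_se=False,
                      maxiter=1, gtol=1e-12)
        assert res.converged is False
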