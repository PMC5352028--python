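"""Single-outcome latent growth curve models (linear or quadratic).

Seven repeated measures ``y0..y6`` load on a latent intercept (loadings all
1) and slope (loadings 0..6, one unit per annual wave); an optional
quadratic factor uses squared loadings.  In the conditional model every
growth factor is regressed on a set of baseline covariates.  Estimation is
ML or FIML through the RAM engine; fit indices are attached from
:mod:`growthsem.fitstats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ram import FitResult, RamModel, fit_ram
from . import fitstats

__all__ = ["GrowthSpec", "build_lgcm", "start_values", "fit_model", "GrowthCurveModel"]

FACTOR_NAMES = ("intercept", "slope", "quad")


@dataclass(frozen=True)
class GrowthSpec:
    """Fixed factor-loading design for a growth model over T annual waves."""

    wave_count: int = 7
    quadratic: bool = False

    @property
    def n_factors(self) -> int:
        return 3 if self.quadratic else 2

    @property
    def loadings(self) -> np.ndarray:
        """(n_factors, T) loading matrix: rows 1, t, t^2."""
        t = np.arange(self.wave_count, dtype=float)
        rows = [np.ones_like(t), t]
        if self.quadratic:
            rows.append(t**2)
        return np.vstack(rows)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return FACTOR_NAMES[: self.n_factors]


def build_lgcm(
    spec: GrowthSpec,
    covariate_names: tuple[str, ...] = (),
    outcome: str = "y",
) -> RamModel:
    """Assemble the RAM matrices for a (conditional) growth curve model.

    Free parameters: factor means/intercepts ``nu_*``, the full factor
    residual covariance ``psi_*``, per-wave residual variances
    ``theta_<outcome><t>``, and (if covariates) regressions
    ``gamma_<factor>_<cov>`` plus profiled covariate moments.
    """
    covariate_names = tuple(covariate_names)
    if len(set(covariate_names)) != len(covariate_names):
        raise ValueError("duplicate covariate names")
    T = spec.wave_count
    indicators = [f"{outcome}{t}" for t in range(T)]
    obs = indicators + list(covariate_names)
    factors = list(spec.factor_names)
    model = RamModel(obs, factors, covariates=covariate_names)

    lam = spec.loadings
    for k, f in enumerate(factors):
        for t in range(T):
            model.set_fixed("A", indicators[t], f, lam[k, t])

    for f in factors:
        model.add_param(f"nu_{f}", "M", f, None, 0.0, "mean")
    for a, f in enumerate(factors):
        model.add_param(f"psi_{f}", "S", f, f, 1.0, "variance")
        for g in factors[:a]:
            model.add_param(f"psi_{g}_{f}", "S", g, f, 0.0, "covariance")
    for t in range(T):
        model.add_param(f"theta_{outcome}{t}", "S", indicators[t], indicators[t], 1.0, "variance")

    for f in factors:
        for c in covariate_names:
            model.add_param(f"gamma_{f}_{c}", "A", f, c, 0.0, "path")
    _add_covariate_moments(model, covariate_names)
    assert model.check_acyclic()
    return model


def _add_covariate_moments(model: RamModel, covariate_names) -> None:
    for i, c in enumerate(covariate_names):
        model.add_param(f"x_mean_{c}", "M", c, None, 0.0, "mean", profiled=True)
        model.add_param(f"x_var_{c}", "S", c, c, 1.0, "variance", profiled=True)
        for j in range(i):
            model.add_param(
                f"x_cov_{covariate_names[j]}_{c}", "S", covariate_names[j], c,
                0.0, "covariance", profiled=True,
            )


def subject_ols(Y: np.ndarray, loadings: np.ndarray):
    """Per-subject OLS growth factors from observed waves (NaN tolerated).

    Returns (n, k) factor estimates (NaN where a subject has fewer observed
    waves than factors) and per-wave residual variances.
    """
    n, T = Y.shape
    k = loadings.shape[0]
    X = loadings.T  # T x k
    est = np.full((n, k), np.nan)
    resid = np.full_like(Y, np.nan)
    obs = ~np.isnan(Y)
    for i in range(n):
        m = obs[i]
        if m.sum() < k + 1:
            continue
        b, *_ = np.linalg.lstsq(X[m], Y[i, m], rcond=None)
        est[i] = b
        resid[i, m] = Y[i, m] - X[m] @ b
    theta = np.nanvar(resid, axis=0)
    return est, theta


def start_values(model: RamModel, spec: GrowthSpec, data: pd.DataFrame, outcome: str = "y"):
    """Deterministic starts: OLS trajectory fits for nu/psi/theta, 0 for gamma."""
    T = spec.wave_count
    Y = data[[f"{outcome}{t}" for t in range(T)]].to_numpy(dtype=float)
    est, theta = subject_ols(Y, spec.loadings)
    ok = ~np.isnan(est).any(axis=1)
    starts: dict[str, float] = {}
    factors = spec.factor_names
    if ok.sum() >= spec.n_factors + 2:
        nu = est[ok].mean(axis=0)
        psi = np.cov(est[ok], rowvar=False)
        psi = np.atleast_2d(psi)
    else:
        nu = np.zeros(spec.n_factors)
        psi = np.eye(spec.n_factors)
    for a, f in enumerate(factors):
        starts[f"nu_{f}"] = float(nu[a])
        starts[f"psi_{f}"] = float(max(psi[a, a], 1e-3))
        for b, g in enumerate(factors[:a]):
            starts[f"psi_{g}_{f}"] = float(psi[b, a])
    for t in range(T):
        v = theta[t] if np.isfinite(theta[t]) and theta[t] > 1e-6 else 0.5
        starts[f"theta_{outcome}{t}"] = float(v)
    return starts


def fit_model(
    model: RamModel,
    data: pd.DataFrame,
    estimator: str = "ml",
    spec: GrowthSpec | None = None,
    outcome: str = "y",
    **options,
) -> FitResult:
    """Fit a growth model; uses OLS-based starts when a spec is given."""
    start = start_values(model, spec, data, outcome) if spec is not None else None
    return fit_ram(model, data, estimator=estimator, start=start, **options)


class GrowthCurveModel(BaseEstimator):
    """Latent growth curve model with a scikit-learn estimator interface.

    Parameters
    ----------
    quadratic : bool
        Add a quadratic growth factor (loadings t^2).
    covariates : sequence of str or None
        Baseline covariate columns; growth factors are regressed on them.
    estimator : {'ml', 'fiml'}
        Complete-case maximum likelihood, or full-information ML over each
        row's observed subvector (missing-at-random).
    wave_count : int
    outcome : str
        Column prefix of the repeated measure (columns ``<outcome>0..6``).
    rmsea_n : {'n-1', 'n'}
        Denominator convention for RMSEA.
    compute_se : bool
        Standard errors from the inverse numerical Hessian.

    Attributes (after ``fit``)
    ----------
    result_ : FitResult
    params_ : pandas.Series of free-parameter estimates
    se_ : pandas.Series
    indices_ : fitstats.FitIndices (chi2, df, CFI, TLI, RMSEA + 90% CI)
    converged_ : bool
    """

    def __init__(
        self,
        quadratic: bool = False,
        covariates=None,
        estimator: str = "ml",
        wave_count: int = 7,
        outcome: str = "y",
        rmsea_n: str = "n-1",
        compute_se: bool = True,
    ):
        self.quadratic = quadratic
        self.covariates = covariates
        self.estimator = estimator
        self.wave_count = wave_count
        self.outcome = outcome
        self.rmsea_n = rmsea_n
        self.compute_se = compute_se

    def fit(self, X: pd.DataFrame, y=None):
        spec = GrowthSpec(self.wave_count, self.quadratic)
        covs = tuple(self.covariates) if self.covariates else ()
        model = build_lgcm(spec, covs, outcome=self.outcome)
        res = fit_model(
            model, X, estimator=self.estimator, spec=spec, outcome=self.outcome,
            compute_se=self.compute_se,
        )
        res.indices = fitstats.evaluate_fit(
            res, X[model.obs_names], rmsea_n=self.rmsea_n
        )
        self.result_ = res
        self.spec_ = spec
        self.params_ = pd.Series({k: res.estimates[k] for k in model.free_names})
        self.se_ = pd.Series(res.se) if res.se else None
        self.loglik_ = res.loglik
        self.chi2_ = res.chi2
        self.df_ = res.df
        self.indices_ = res.indices
        self.converged_ = res.converged
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Empirical-Bayes-free prediction: per-subject OLS factor scores
        times the loading design (mean trajectory for rows with too few
        observed waves)."""
        spec = self.spec_
        Y = X[[f"{self.outcome}{t}" for t in range(spec.wave_count)]].to_numpy(float)
        est, _ = subject_ols(Y, spec.loadings)
        nu = np.array([self.params_[f"nu_{f}"] for f in spec.factor_names])
        est = np.where(np.isnan(est), nu, est)
        return est @ spec.loadings
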