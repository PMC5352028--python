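"""Three-process parallel latent growth curve model (BMI, PA, HDB).

Each process has seven annual indicators loading on a linear growth
structure.  The BMI growth factors are regressed on the behavior factors:

* cross-sectional 'a' paths: Intercept_PA, Intercept_HDB -> Intercept_BMI
* prospective 'b' paths:     Intercept_PA, Intercept_HDB -> Slope_BMI
* parallel 'c' paths:        Slope_PA, Slope_HDB         -> Slope_BMI

The four predictor factors covary freely; BMI factor disturbances covary
with each other but not with the predictors.  Time-varying confounding of
the behaviors is absorbed by free within-wave residual covariances among
the three processes (``wave_residual_policy='free'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import fitstats
from .growth import GrowthSpec, _add_covariate_moments, subject_ols
from .ram import FitResult, RamModel, fit_ram

__all__ = [
    "PROCESSES",
    "build_parallel_lgcm",
    "parallel_start_values",
    "AssociationPaths",
    "extract_associations",
    "interpretation_table",
    "ParallelGrowthCurveModel",
]

PROCESSES = ("bmi", "pa", "hdb")
_PRED_FACTORS = ("int_pa", "slope_pa", "int_hdb", "slope_hdb")
_BMI_FACTORS = ("int_bmi", "slope_bmi")
_PATH_NAMES = ("a_pa", "a_hdb", "b_pa", "b_hdb", "c_pa", "c_hdb")


def build_parallel_lgcm(
    covariate_names: tuple[str, ...] = (),
    wave_residual_policy: str = "free",
    covariates_predict: str = "all",
    wave_count: int = 7,
) -> RamModel:
    """Assemble the parallel-process model.

    ``wave_residual_policy`` in {'none', 'free'} controls whether the three
    processes' time-specific residuals may covary within a wave.
    ``covariates_predict`` in {'all', 'bmi'} selects which growth factors
    the baseline covariates regress on.
    """
    if wave_residual_policy not in ("none", "free"):
        raise ValueError("wave_residual_policy must be 'none' or 'free'")
    if covariates_predict not in ("all", "bmi"):
        raise ValueError("covariates_predict must be 'all' or 'bmi'")
    covariate_names = tuple(covariate_names)
    if len(set(covariate_names)) != len(covariate_names):
        raise ValueError("duplicate covariate names")
    T = wave_count
    indicators = {pr: [f"{pr}{t}" for t in range(T)] for pr in PROCESSES}
    obs = indicators["bmi"] + indicators["pa"] + indicators["hdb"] + list(covariate_names)
    factors = list(_BMI_FACTORS) + list(_PRED_FACTORS)
    model = RamModel(obs, factors, covariates=covariate_names)

    t_load = np.arange(T, dtype=float)
    for pr, (fi, fs) in zip(
        PROCESSES, [("int_bmi", "slope_bmi"), ("int_pa", "slope_pa"), ("int_hdb", "slope_hdb")]
    ):
        for t in range(T):
            model.set_fixed("A", indicators[pr][t], fi, 1.0)
            model.set_fixed("A", indicators[pr][t], fs, t_load[t])

    # factor means / structural intercepts
    for f in factors:
        model.add_param(f"nu_{f}", "M", f, None, 0.0, "mean")

    # structural a/b/c paths
    model.add_param("a_pa", "A", "int_bmi", "int_pa", 0.0, "path")
    model.add_param("a_hdb", "A", "int_bmi", "int_hdb", 0.0, "path")
    model.add_param("b_pa", "A", "slope_bmi", "int_pa", 0.0, "path")
    model.add_param("b_hdb", "A", "slope_bmi", "int_hdb", 0.0, "path")
    model.add_param("c_pa", "A", "slope_bmi", "slope_pa", 0.0, "path")
    model.add_param("c_hdb", "A", "slope_bmi", "slope_hdb", 0.0, "path")

    # predictor factor covariance block (free 4x4)
    for i, f in enumerate(_PRED_FACTORS):
        model.add_param(f"psi_{f}", "S", f, f, 0.5, "variance")
        for g in _PRED_FACTORS[:i]:
            model.add_param(f"psi_{g}_{f}", "S", g, f, 0.0, "covariance")
    # BMI disturbances
    model.add_param("psi_int_bmi", "S", "int_bmi", "int_bmi", 4.0, "variance")
    model.add_param("psi_slope_bmi", "S", "slope_bmi", "slope_bmi", 0.1, "variance")
    model.add_param("psi_int_bmi_slope_bmi", "S", "int_bmi", "slope_bmi", 0.0, "covariance")

    # wave residual variances (+ optional within-wave covariances)
    for pr in PROCESSES:
        for t in range(T):
            model.add_param(f"theta_{pr}{t}", "S", f"{pr}{t}", f"{pr}{t}", 0.5, "variance")
    if wave_residual_policy == "free":
        for t in range(T):
            for i, pr1 in enumerate(PROCESSES):
                for pr2 in PROCESSES[:i]:
                    model.add_param(
                        f"rescov_{pr2}_{pr1}_{t}", "S", f"{pr2}{t}", f"{pr1}{t}",
                        0.0, "covariance",
                    )

    targets = factors if covariates_predict == "all" else list(_BMI_FACTORS)
    for f in targets:
        for c in covariate_names:
            model.add_param(f"gamma_{f}_{c}", "A", f, c, 0.0, "path")
    _add_covariate_moments(model, covariate_names)
    assert model.check_acyclic()
    return model


def parallel_start_values(model: RamModel, data: pd.DataFrame, wave_count: int = 7):
    """OLS-based deterministic starts for the parallel model.

    Per-subject OLS intercept/slope per process give factor means and the
    predictor covariance block; structural paths start at 0, so the BMI
    disturbance block starts at the marginal BMI factor covariance.
    """
    spec = GrowthSpec(wave_count, quadratic=False)
    est = {}
    theta = {}
    for pr in PROCESSES:
        Y = data[[f"{pr}{t}" for t in range(wave_count)]].to_numpy(dtype=float)
        est[pr], theta[pr] = subject_ols(Y, spec.loadings)
    starts: dict[str, float] = {}
    fac_cols = {
        "int_bmi": est["bmi"][:, 0], "slope_bmi": est["bmi"][:, 1],
        "int_pa": est["pa"][:, 0], "slope_pa": est["pa"][:, 1],
        "int_hdb": est["hdb"][:, 0], "slope_hdb": est["hdb"][:, 1],
    }
    F = np.column_stack(list(fac_cols.values()))
    ok = ~np.isnan(F).any(axis=1)
    names = list(fac_cols)
    if ok.sum() > 10:
        mean = F[ok].mean(axis=0)
        cov = np.cov(F[ok], rowvar=False)
    else:
        mean = np.zeros(6)
        cov = np.eye(6)
    for i, f in enumerate(names):
        starts[f"nu_{f}"] = float(mean[i])
    for i, f in enumerate(_PRED_FACTORS):
        ii = names.index(f)
        starts[f"psi_{f}"] = float(max(cov[ii, ii], 1e-3))
        for g in _PRED_FACTORS[: _PRED_FACTORS.index(f)]:
            starts[f"psi_{g}_{f}"] = float(cov[names.index(g), ii])
    starts["psi_int_bmi"] = float(max(cov[0, 0], 1e-3))
    starts["psi_slope_bmi"] = float(max(cov[1, 1], 1e-3))
    starts["psi_int_bmi_slope_bmi"] = float(cov[0, 1])
    for pr in PROCESSES:
        for t in range(wave_count):
            v = theta[pr][t]
            starts[f"theta_{pr}{t}"] = float(v) if np.isfinite(v) and v > 1e-6 else 0.3
    return starts


@dataclass
class AssociationPaths:
    """The six structural coefficients of the parallel model.

    cross_sectional: baseline-BMI units per baseline PCS unit (a paths);
    prospective: BMI-slope units per baseline PCS unit (b paths);
    parallel: BMI-slope units per PCS-slope unit (c paths).
    Each entry is (PA predictor, HDB predictor) of (estimate, se, lo95, hi95).
    """

    cross_sectional: tuple
    prospective: tuple
    parallel: tuple

    def to_frame(self) -> pd.DataFrame:
        rows = []
        labels = {
            "cross_sectional": (
                "Intercept_PA -> Intercept_BMI", "Intercept_HDB -> Intercept_BMI"),
            "prospective": (
                "Intercept_PA -> Slope_BMI", "Intercept_HDB -> Slope_BMI"),
            "parallel": ("Slope_PA -> Slope_BMI", "Slope_HDB -> Slope_BMI"),
        }
        for family in ("cross_sectional", "prospective", "parallel"):
            for lab, (est, se, lo, hi) in zip(labels[family], getattr(self, family)):
                rows.append(
                    {"family": family, "path": lab, "estimate": est,
                     "se": se, "ci_lo": lo, "ci_hi": hi}
                )
        return pd.DataFrame(rows)


_Z95 = 1.959963984540054


def extract_associations(fit: FitResult) -> AssociationPaths:
    """Pull the a/b/c coefficients (with SE and normal-theory 95% CI)."""
    missing = [n for n in _PATH_NAMES if n not in fit.estimates]
    if missing:
        raise ValueError(f"fit lacks structural parameters: {missing}")

    def entry(name):
        est = fit.estimates[name]
        se = fit.se.get(name, np.nan) if fit.se else np.nan
        se = np.nan if se is None else se
        return (est, se, est - _Z95 * se, est + _Z95 * se)

    return AssociationPaths(
        cross_sectional=(entry("a_pa"), entry("a_hdb")),
        prospective=(entry("b_pa"), entry("b_hdb")),
        parallel=(entry("c_pa"), entry("c_hdb")),
    )


_INTERPRETATIONS = {
    ("cross_sectional", "pa"): (
        "change in baseline BMI (kg/m^2) per unit change in baseline PCS_PA"),
    ("cross_sectional", "hdb"): (
        "change in baseline BMI (kg/m^2) per unit change in baseline PCS_HDB"),
    ("prospective", "pa"): (
        "change in BMI growth rate (kg/m^2/year) per unit change in baseline PCS_PA"),
    ("prospective", "hdb"): (
        "change in BMI growth rate (kg/m^2/year) per unit change in baseline PCS_HDB"),
    ("parallel", "pa"): (
        "change in BMI growth rate (kg/m^2/year) per unit change in the growth rate of PCS_PA"),
    ("parallel", "hdb"): (
        "change in BMI growth rate (kg/m^2/year) per unit change in the growth rate of PCS_HDB"),
}


def interpretation_table(paths: AssociationPaths) -> pd.DataFrame:
    """Six labeled rows pairing each coefficient with its unit-change reading."""
    df = paths.to_frame()
    df["predictor"] = ["pa", "hdb"] * 3
    df["interpretation"] = [
        _INTERPRETATIONS[(fam, pred)] for fam, pred in zip(df["family"], df["predictor"])
    ]
    return df


class ParallelGrowthCurveModel(BaseEstimator):
    """Parallel-process growth model with a scikit-learn estimator surface.

    ``fit`` expects a wide frame with columns ``bmi0..6, pa0..6, hdb0..6``
    plus any covariates.  Fitted attributes include ``associations_`` (the
    a/b/c paths), ``params_``, ``indices_`` and ``converged_``.
    """

    def __init__(
        self,
        covariates=None,
        wave_residual_policy: str = "free",
        covariates_predict: str = "all",
        estimator: str = "ml",
        wave_count: int = 7,
        rmsea_n: str = "n-1",
        compute_se: bool = True,
    ):
        self.covariates = covariates
        self.wave_residual_policy = wave_residual_policy
        self.covariates_predict = covariates_predict
        self.estimator = estimator
        self.wave_count = wave_count
        self.rmsea_n = rmsea_n
        self.compute_se = compute_se

    def fit(self, X: pd.DataFrame, y=None):
        covs = tuple(self.covariates) if self.covariates else ()
        model = build_parallel_lgcm(
            covs,
            wave_residual_policy=self.wave_residual_policy,
            covariates_predict=self.covariates_predict,
            wave_count=self.wave_count,
        )
        start = parallel_start_values(model, X, self.wave_count)
        res = fit_ram(
            model, X, estimator=self.estimator, start=start, compute_se=self.compute_se
        )
        res.indices = fitstats.evaluate_fit(res, rmsea_n=self.rmsea_n)
        self.result_ = res
        self.params_ = pd.Series({k: res.estimates[k] for k in model.free_names})
        self.se_ = pd.Series(res.se) if res.se else None
        self.associations_ = extract_associations(res)
        self.loglik_ = res.loglik
        self.chi2_ = res.chi2
        self.df_ = res.df
        self.indices_ = res.indices
        self.converged_ = res.converged
        return self
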