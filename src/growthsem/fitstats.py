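"""Global model-fit statistics: likelihood-ratio chi-square, independence
baseline, CFI, TLI, RMSEA with 90% noncentrality CI, adequacy flag, and the
linear-vs-quadratic model comparison.

The chi-square is the likelihood-ratio statistic against the saturated
model, 2(l_sat - l_model), so one definition serves ML and FIML; with
complete data it equals n * F_ML (the classical (n-1) * F_ML differs by the
n/(n-1) factor only).  RMSEA uses the (n-1) denominator by default; the
plain-n convention (as used by some SEM programs) is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .ram import FitResult, independence_fit

__all__ = [
    "FitIndices",
    "chi_square",
    "baseline_model",
    "cfi_tli",
    "rmsea_ci",
    "adequacy",
    "evaluate_fit",
    "compare_linear_quadratic",
    "ModelComparison",
]


@dataclass
class FitIndices:
    chi2: float
    df: int
    cfi: float
    tli: float | None
    rmsea: float
    rmsea_lo90: float
    rmsea_hi90: float
    adequate: bool | None

    def row(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "rmsea": self.rmsea,
            "rmsea_lo90": self.rmsea_lo90,
            "rmsea_hi90": self.rmsea_hi90,
            "cfi": self.cfi,
            "tli": self.tli,
            "adequate": self.adequate,
        }


def chi_square(loglik_model: float, loglik_saturated: float, p: int, n_free: int):
    """Likelihood-ratio chi-square against the saturated model, and its df.

    df = p(p+3)/2 - n_free for a mean+covariance structure on p observed
    variables.
    """
    raw = 2.0 * (loglik_saturated - loglik_model)
    if raw < -1e-6 * (1 + abs(loglik_saturated)):
        raise ValueError("saturated loglik below model loglik; bad optimum upstream")
    return max(raw, 0.0), p * (p + 3) // 2 - n_free


def baseline_model(data: np.ndarray):
    """Independence baseline (free means/variances, zero covariances).

    Valid under FIML because the independence likelihood factorizes per
    variable.  Returns (loglik, df_baseline).
    """
    Y = np.asarray(data, dtype=float)
    p = Y.shape[1]
    ll, n_free = independence_fit(Y)
    df_b = p * (p + 3) // 2 - n_free
    return ll, df_b


def cfi_tli(chi2: float, df: int, chi2_baseline: float, df_baseline: int):
    """Comparative fit index and Tucker-Lewis index.

    CFI = 1 - max(chi2-df,0)/max(chi2-df, chi2_b-df_b, 0) (1 when both 0);
    TLI = (chi2_b/df_b - chi2/df) / (chi2_b/df_b - 1); TLI is None with a
    warning when the baseline ratio equals 1.
    """
    if df <= 0 or df_baseline <= 0:
        raise ValueError("df and df_baseline must be positive")
    num = max(chi2 - df, 0.0)
    den = max(chi2 - df, chi2_baseline - df_baseline, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    ratio_b = chi2_baseline / df_baseline
    if abs(ratio_b - 1.0) < 1e-12:
        warnings.warn("baseline chi2/df equals 1; TLI undefined")
        tli = None
    else:
        tli = (ratio_b - chi2 / df) / (ratio_b - 1.0)
    return cfi, tli


def rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90, use_n: bool = False):
    """RMSEA point estimate and noncentrality-based confidence bounds.

    point = sqrt(max(chi2-df, 0) / (df * (n-1))) (or /(df*n) when
    ``use_n``).  Bounds invert the noncentral chi-square cdf:
    cdf(chi2; df, lambda) = (1+level)/2 gives the lower bound, (1-level)/2
    the upper; bounds are sqrt(lambda / (df*(n-1))), clamped at 0.
    """
    if df < 1 or n < 2:
        raise ValueError("need df >= 1 and n >= 2")
    denom = df * (n if use_n else n - 1)
    point = float(np.sqrt(max(chi2 - df, 0.0) / denom))

    def bound(prob):
        # find lambda with ncx2.cdf(chi2, df, lambda) == prob
        if stats.chi2.cdf(chi2, df) <= prob:
            return 0.0
        lo, hi = 0.0, max(4.0 * chi2, 10.0)
        while stats.ncx2.cdf(chi2, df, hi) > prob:
            hi *= 2
            if hi > 1e8:
                warnings.warn("RMSEA bound root-finding failed")
                return np.nan
        lam = optimize.brentq(
            lambda l: stats.ncx2.cdf(chi2, df, l) - prob, lo, hi, xtol=1e-10
        )
        return lam

    hi_tail = (1.0 - level) / 2.0
    lam_lo = bound(1.0 - hi_tail)
    lam_hi = bound(hi_tail)
    lo = float(np.sqrt(lam_lo / denom)) if np.isfinite(lam_lo) else np.nan
    hi = float(np.sqrt(lam_hi / denom)) if np.isfinite(lam_hi) else np.nan
    return point, lo, hi


def adequacy(cfi: float, tli: float | None, rmsea: float) -> bool | None:
    """Conventional adequacy rule: CFI >= .90, TLI >= .90 and RMSEA <= .08."""
    if tli is None or any(x is None or np.isnan(x) for x in (cfi, rmsea)):
        return None
    return bool(cfi >= 0.90 and tli >= 0.90 and rmsea <= 0.08)


def evaluate_fit(result: FitResult, data=None, rmsea_n: str = "n-1") -> FitIndices:
    """Compute all indices for a fitted model.

    ``data`` defaults to the rows the fit actually used, so the baseline
    model sees the same missingness pattern.
    """
    Y = result.used_data if data is None else np.asarray(data, dtype=float)
    ll_b, df_b = baseline_model(Y)
    chi2_b = max(2.0 * (result.loglik_saturated - ll_b), 0.0)
    cfi, tli = cfi_tli(result.chi2, result.df, chi2_b, df_b)
    point, lo, hi = rmsea_ci(
        result.chi2, result.df, result.n_effective, use_n=(rmsea_n == "n")
    )
    return FitIndices(
        chi2=result.chi2,
        df=result.df,
        cfi=cfi,
        tli=tli,
        rmsea=point,
        rmsea_lo90=lo,
        rmsea_hi90=hi,
        adequate=adequacy(cfi, tli, point),
    )


@dataclass
class ModelComparison:
    lr_chi2: float
    lr_df: int
    lr_p: float
    wald_chi2: float | None
    wald_p: float | None
    preferred: str  # 'linear' or 'quadratic'


def compare_linear_quadratic(fit_linear: FitResult, fit_quadratic: FitResult) -> ModelComparison:
    """Likelihood-ratio comparison of nested linear vs quadratic growth fits.

    The quadratic model is preferred only when the LR test rejects at 0.05
    AND the quadratic mean and variance are jointly significant (Wald test
    on (nu_quad, psi_quad)); otherwise the linear model wins on parsimony.
    """
    if fit_linear.data_hash != fit_quadratic.data_hash:
        raise ValueError("fits are not on identical data")
    lr = 2.0 * (fit_quadratic.loglik - fit_linear.loglik)
    lr = max(lr, 0.0)
    lr_df = fit_quadratic.model.n_free - fit_linear.model.n_free
    if lr_df <= 0:
        raise ValueError("quadratic model must have more free parameters")
    lr_p = float(stats.chi2.sf(lr, lr_df))

    wald = wald_p = None
    if fit_quadratic.vcov is not None:
        names = ["nu_quad", "psi_quad"]
        if all(n in fit_quadratic.vcov.index for n in names):
            v = np.array([fit_quadratic.estimates[n] for n in names])
            V = fit_quadratic.vcov.loc[names, names].to_numpy()
            try:
                wald = float(v @ np.linalg.solve(V, v))
                wald_p = float(stats.chi2.sf(wald, len(names)))
            except np.linalg.LinAlgError:
                pass
    quad_wins = lr_p < 0.05 and (wald_p is not None and wald_p < 0.05)
    return ModelComparison(
        lr_chi2=lr, lr_df=lr_df, lr_p=lr_p,
        wald_chi2=wald, wald_p=wald_p,
        preferred="quadratic" if quad_wins else "linear",
    )
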