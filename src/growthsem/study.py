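"""Reference estimates from the motivating 7-year workplace-wellness cohort.

These are the published stratum-specific quantities (six strata: gender x
baseline weight status) that the synthetic-cohort generator uses as
generating truths and the validation suite uses as recovery targets:

* stratum sizes and baseline covariate marginals (age, race, education,
  family income, smoking, alcohol),
* latent growth parameter estimates per process (BMI, PCS_PA, PCS_HDB):
  mean intercept, mean slope (per year), and intercept-slope covariance,
* the six structural association paths of the parallel growth model
  (cross-sectional a, prospective b, parallel c; PA and HDB predictors),
  each with its 95% confidence interval.

Units: BMI in kg/m^2 (slopes kg/m^2 per year); PA/HDB on the standardized
principal-component-score scale.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GENDERS",
    "WEIGHT_STATUSES",
    "STRATA",
    "CovariateMarginals",
    "ProcessEstimates",
    "PathEstimate",
    "StratumReference",
    "se_from_ci",
]

GENDERS = ("male", "female")
WEIGHT_STATUSES = ("normal", "overweight", "obese")


@dataclass(frozen=True)
class CovariateMarginals:
    """Baseline covariate marginals for one stratum."""

    age: tuple[float, float]        # mean, SD (years)
    race_other: float               # P(race != non-Hispanic white)
    education: tuple[float, ...]    # P(levels 1..4), sums to 1
    income: tuple[float, ...]       # P(levels 1..4), sums to 1
    smoking: float                  # P(current smoker)
    alcohol: tuple[float, float]    # mean, SD (drinks/day)


@dataclass(frozen=True)
class ProcessEstimates:
    """Published growth parameters for one outcome process in one stratum."""

    intercept: float    # mean of the latent intercept factor
    slope: float        # mean of the latent slope factor (per year)
    cov: float          # intercept-slope covariance


@dataclass(frozen=True)
class PathEstimate:
    est: float
    ci: tuple[float, float]

    @property
    def se(self) -> float:
        return se_from_ci(*self.ci)


def se_from_ci(lo: float, hi: float, level: float = 0.95) -> float:
    """Standard error implied by a normal-theory confidence interval."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    return (hi - lo) / (2 * z)


@dataclass(frozen=True)
class StratumReference:
    n: int
    covariates: CovariateMarginals
    bmi: ProcessEstimates
    pa: ProcessEstimates
    hdb: ProcessEstimates
    # structural paths, (PA predictor, HDB predictor) per family
    a: tuple[PathEstimate, PathEstimate]   # intercept -> BMI intercept
    b: tuple[PathEstimate, PathEstimate]   # intercept -> BMI slope
    c: tuple[PathEstimate, PathEstimate]   # slope -> BMI slope


def _p(est, lo, hi):
    return PathEstimate(est, (lo, hi))


def _norm(v):
    s = sum(v)
    return tuple(x / s for x in v)


STRATA: dict[tuple[str, str], StratumReference] = {
    ("male", "normal"): StratumReference(
        n=223,
        covariates=CovariateMarginals(
            age=(41.2, 9.8), race_other=0.099,
            education=_norm((17.5, 13.0, 46.6, 22.9)),
            income=_norm((19.7, 18.4, 19.7, 42.2)),
            smoking=0.139, alcohol=(3.0, 3.2),
        ),
        bmi=ProcessEstimates(23.46, 0.18, 0.09),
        pa=ProcessEstimates(0.16, -0.01, -0.03),
        hdb=ProcessEstimates(-0.06, -0.01, -0.01),
        a=(_p(-0.08, -0.39, 0.23), _p(-0.17, -0.49, 0.16)),
        b=(_p(-0.02, -0.07, 0.04), _p(0.04, -0.02, 0.10)),
        c=(_p(-0.50, -1.09, 0.10), _p(-0.49, -1.41, 0.44)),
    ),
    ("male", "overweight"): StratumReference(
        n=530,
        covariates=CovariateMarginals(
            age=(44.5, 9.7), race_other=0.151,
            education=_norm((18.5, 22.5, 45.7, 13.4)),
            income=_norm((14.7, 16.4, 24.3, 44.5)),
            smoking=0.119, alcohol=(3.4, 3.7),
        ),
        bmi=ProcessEstimates(27.49, 0.11, 0.14),
        pa=ProcessEstimates(0.01, 0.02, -0.03),
        hdb=ProcessEstimates(-0.14, 0.01, -0.01),
        a=(_p(-0.08, -0.29, 0.12), _p(0.08, -0.14, 0.29)),
        b=(_p(-0.03, -0.08, 0.02), _p(0.06, 0.00, 0.11)),
        c=(_p(-0.45, -1.08, 0.18), _p(-0.84, -1.69, 0.01)),
    ),
    ("male", "obese"): StratumReference(
        n=319,
        covariates=CovariateMarginals(
            age=(44.0, 9.0), race_other=0.097,
            education=_norm((20.4, 25.7, 44.5, 9.4)),
            income=_norm((11.6, 15.4, 21.9, 51.1)),
            smoking=0.132, alcohol=(2.6, 3.1),
        ),
        bmi=ProcessEstimates(33.32, 0.06, 0.15),
        pa=ProcessEstimates(-0.31, 0.03, -0.04),
        hdb=ProcessEstimates(-0.34, 0.03, -0.02),
        a=(_p(-1.51, -2.23, -0.79), _p(0.23, -0.43, 0.88)),
        b=(_p(0.05, -0.05, 0.14), _p(-0.07, -0.15, 0.02)),
        c=(_p(-1.70, -2.66, -0.73), _p(-1.98, -3.77, -0.18)),
    ),
    ("female", "normal"): StratumReference(
        n=663,
        covariates=CovariateMarginals(
            age=(40.1, 10.6), race_other=0.062,
            education=_norm((10.6, 18.6, 56.6, 14.3)),
            income=_norm((18.4, 22.3, 17.5, 41.8)),
            smoking=0.092, alcohol=(2.1, 2.4),
        ),
        bmi=ProcessEstimates(22.31, 0.20, 0.14),
        pa=ProcessEstimates(0.28, -0.002, -0.03),
        hdb=ProcessEstimates(0.23, 0.001, -0.01),
        a=(_p(-0.03, -0.26, 0.19), _p(-0.22, -0.48, 0.04)),
        b=(_p(-0.01, -0.05, 0.04), _p(-0.04, -0.09, 0.02)),
        c=(_p(-0.75, -1.20, -0.31), _p(-0.52, -1.23, 0.20)),
    ),
    ("female", "overweight"): StratumReference(
        n=405,
        covariates=CovariateMarginals(
            age=(43.1, 10.3), race_other=0.111,
            education=_norm((10.6, 27.7, 46.7, 15.1)),
            income=_norm((18.0, 20.3, 23.2, 38.5)),
            smoking=0.101, alcohol=(2.1, 2.8),
        ),
        bmi=ProcessEstimates(27.33, 0.17, 0.20),
        pa=ProcessEstimates(0.06, 0.002, -0.04),
        hdb=ProcessEstimates(0.12, -0.01, -0.03),
        a=(_p(-0.37, -0.61, -0.14), _p(-0.25, -0.52, 0.02)),
        b=(_p(-0.04, -0.11, 0.03), _p(0.04, -0.04, 0.13)),
        c=(_p(-1.85, -2.75, -0.94), _p(-2.46, -3.57, -1.36)),
    ),
    ("female", "obese"): StratumReference(
        n=439,
        covariates=CovariateMarginals(
            age=(43.9, 9.6), race_other=0.125,
            education=_norm((16.0, 32.4, 41.9, 9.8)),
            income=_norm((26.7, 28.3, 20.1, 25.1)),
            smoking=0.128, alcohol=(1.2, 2.0),
        ),
        bmi=ProcessEstimates(35.73, 0.07, -0.04),
        pa=ProcessEstimates(-0.36, 0.004, -0.03),
        hdb=ProcessEstimates(-0.23, 0.01, -0.02),
        a=(_p(-1.83, -2.71, -0.95), _p(-0.58, -1.38, 0.22)),
        b=(_p(0.05, -0.08, 0.18), _p(0.06, -0.06, 0.18)),
        c=(_p(-2.78, -4.09, -1.46), _p(-3.08, -4.77, -1.38)),
    ),
}
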