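"""Synthetic longitudinal cohorts with parallel growth structure.

The generator emulates the study conditions the estimators assume: six
gender x baseline-weight-status strata; within each stratum three parallel
linear growth processes (BMI in kg/m^2, and continuous PA / HDB composite
scores) in which the BMI growth factors are structural functions of the
behavior factors (a/b/c paths); baseline covariates drawn from published
stratum marginals; Likert measurement of the behaviors via thresholded
latent items; and missing-at-random wave nonresponse (monotone dropout
plus intermittency, logistic in baseline age and smoking).

Published stratum estimates (means, intercept-slope covariances, paths)
are the generating truths; unprinted scales use documented defaults: BMI
disturbance SDs 3.0 (intercept) and 0.3 (slope) with residual SD 1.0;
PA/HDB disturbance SDs 0.85 and 0.12 with residual SD 0.55.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from . import study
from .panel import ANALYSIS_VARS, HDB_ITEMS, PA_ITEMS, PanelDataset

__all__ = [
    "GrowthParams",
    "ParallelParams",
    "LikertItemSpec",
    "LikertSpec",
    "MissingnessSpec",
    "StratumConfig",
    "SimulationConfig",
    "simulate_growth_factors",
    "simulate_trajectories",
    "discretize_to_likert",
    "impose_mar_missingness",
    "simulate_parallel_cohort",
    "simulate_stratum",
    "factor_moments",
    "implied_observed_moments",
    "default_params",
    "default_config",
]

T_WAVES = 7

# documented default scales for quantities the reference tables do not print
BMI_INT_SD = 3.0
BMI_SLOPE_SD = 0.3
BMI_RESID_SD = 1.0
PCS_INT_SD = 0.85
PCS_SLOPE_SD = 0.12
PCS_RESID_SD = 0.55

#: unique-noise share of each latent Likert item, calibrated once so the
#: first principal component of the discretized items carries ~71% (PA) and
#: ~56% (HDB) of the item variance.
PA_NOISE_SHARE = 0.38
HDB_NOISE_SHARE = 0.62


@dataclass
class GrowthParams:
    """Generating parameters of one linear growth process.

    nu : (2,) marginal means of (intercept, slope).
    Gamma : (2, M) covariate coefficients (deviation-coded) or None.
    Psi : (2, 2) disturbance covariance of the growth factors.
    theta : (T,) time-specific residual variances.
    """

    nu: np.ndarray
    Psi: np.ndarray
    theta: np.ndarray
    Gamma: np.ndarray | None = None

    def __post_init__(self):
        self.nu = np.asarray(self.nu, dtype=float)
        self.Psi = np.asarray(self.Psi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.Gamma is not None:
            self.Gamma = np.asarray(self.Gamma, dtype=float)
        if not np.allclose(self.Psi, self.Psi.T):
            raise ValueError("Psi must be symmetric")
        if np.linalg.eigvalsh(self.Psi).min() < -1e-10:
            raise ValueError("Psi must be positive semidefinite")
        if (self.theta < 0).any():
            raise ValueError("theta must be nonnegative")


def simulate_growth_factors(params: GrowthParams, covariates, n: int, rng) -> np.ndarray:
    """Draw (n, k) growth factors eta = nu + Gamma x + zeta, zeta ~ N(0, Psi)."""
    k = len(params.nu)
    mean = np.tile(params.nu, (n, 1))
    if params.Gamma is not None:
        X = np.asarray(covariates, dtype=float)
        if len(X) != n:
            raise ValueError("covariates must have length n")
        mean = mean + X @ params.Gamma.T
    zeta = rng.multivariate_normal(np.zeros(k), params.Psi, size=n, method="cholesky") \
        if np.linalg.eigvalsh(params.Psi).min() > 1e-12 else \
        rng.multivariate_normal(np.zeros(k), params.Psi, size=n, method="svd")
    return mean + zeta


def simulate_trajectories(factors, loadings, theta, rng) -> np.ndarray:
    """y_ti = sum_k lambda_kt eta_ki + eps_ti with eps_ti ~ N(0, theta_t)."""
    eta = np.asarray(factors, dtype=float)
    lam = np.asarray(loadings, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if lam.shape[0] != eta.shape[1]:
        raise ValueError("loadings rows must match factor count")
    if (theta < 0).any():
        raise ValueError("theta must be nonnegative")
    mean = eta @ lam
    eps = rng.standard_normal(mean.shape) * np.sqrt(theta)
    return mean + eps


@dataclass
class ParallelParams:
    """Generating parameters for the three-process parallel structure.

    The BMI factors are built structurally from the behavior factors:
    Int_BMI = nu0* + a.(predictor intercepts) + zeta0 and
    Slope_BMI = nu1* + b.(predictor intercepts) + c.(predictor slopes) +
    zeta1, with the structural intercepts nu* derived so the *marginal*
    BMI factor means equal ``bmi.nu``.
    """

    bmi: GrowthParams
    pa: GrowthParams
    hdb: GrowthParams
    paths_a: tuple[float, float] = (0.0, 0.0)
    paths_b: tuple[float, float] = (0.0, 0.0)
    paths_c: tuple[float, float] = (0.0, 0.0)
    predictor_factor_cov: np.ndarray | None = None  # (4,4): int_pa, slope_pa, int_hdb, slope_hdb
    wave_residual_cov: np.ndarray | None = None     # (3,3) cross-process residual cov per wave

    def pred_cov(self) -> np.ndarray:
        if self.predictor_factor_cov is not None:
            P = np.asarray(self.predictor_factor_cov, dtype=float)
        else:
            P = np.zeros((4, 4))
            P[:2, :2] = self.pa.Psi
            P[2:, 2:] = self.hdb.Psi
        return P

    def path_matrix(self) -> np.ndarray:
        a1, a2 = self.paths_a
        b1, b2 = self.paths_b
        c1, c2 = self.paths_c
        return np.array([[a1, 0.0, a2, 0.0], [b1, c1, b2, c2]])


def factor_moments(pp: ParallelParams):
    """Marginal mean and covariance of the six growth factors, ordered
    (int_bmi, slope_bmi, int_pa, slope_pa, int_hdb, slope_hdb), plus the
    structural BMI intercepts nu*."""
    m_pred = np.array([pp.pa.nu[0], pp.pa.nu[1], pp.hdb.nu[0], pp.hdb.nu[1]])
    B = pp.path_matrix()
    P = pp.pred_cov()
    nu_star = pp.bmi.nu - B @ m_pred
    mean = np.concatenate([pp.bmi.nu, m_pred])
    cov = np.zeros((6, 6))
    cov[:2, :2] = B @ P @ B.T + pp.bmi.Psi
    cov[:2, 2:] = B @ P
    cov[2:, :2] = cov[:2, 2:].T
    cov[2:, 2:] = P
    return mean, cov, nu_star


def implied_observed_moments(pp: ParallelParams, T: int = T_WAVES):
    """Implied (Sigma, mu) of the 21 repeated measures, ordered BMI waves,
    then PA, then HDB.  Raises if the implied covariance is not positive
    definite."""
    mean, cov, _ = factor_moments(pp)
    t = np.arange(T, dtype=float)
    lam1 = np.column_stack([np.ones(T), t])  # T x 2
    Lam = np.zeros((3 * T, 6))
    Lam[:T, 0:2] = lam1
    Lam[T:2 * T, 2:4] = lam1
    Lam[2 * T:, 4:6] = lam1
    Sigma = Lam @ cov @ Lam.T
    thetas = [pp.bmi.theta, pp.pa.theta, pp.hdb.theta]
    W = pp.wave_residual_cov
    for t_i in range(T):
        for a in range(3):
            Sigma[a * T + t_i, a * T + t_i] += thetas[a][t_i]
            if W is not None:
                for b in range(a):
                    Sigma[a * T + t_i, b * T + t_i] += W[a, b]
                    Sigma[b * T + t_i, a * T + t_i] += W[a, b]
    mu = Lam @ mean
    np.linalg.cholesky(Sigma)  # parameter error if not PD
    return Sigma, mu


@dataclass
class LikertItemSpec:
    column: str
    n_categories: int
    first_level: int = 1
    loading: float = 1.0
    thresholds: np.ndarray | None = None  # standardized-scale cuts; default equal-probability

    def cuts(self) -> np.ndarray:
        if self.thresholds is not None:
            c = np.asarray(self.thresholds, dtype=float)
        else:
            k = self.n_categories
            c = norm.ppf(np.arange(1, k) / k)
        if np.any(np.diff(c) <= 0):
            raise ValueError(f"thresholds for {self.column} must be strictly increasing")
        return c


@dataclass
class LikertSpec:
    """Measurement model mapping continuous process scores to item batteries."""

    pa_items: list[LikertItemSpec] = field(default_factory=lambda: [
        LikertItemSpec("pa_aerobic", 8, first_level=0),
        LikertItemSpec("pa_general", 6),
        LikertItemSpec("pa_strength", 4),
    ])
    hdb_items: list[LikertItemSpec] = field(default_factory=lambda: [
        LikertItemSpec("hdb_fat", 5),
        LikertItemSpec("hdb_grains", 5),
        LikertItemSpec("hdb_protein", 5),
    ])
    pa_noise_share: float = PA_NOISE_SHARE
    hdb_noise_share: float = HDB_NOISE_SHARE


def discretize_to_likert(score, item_specs, noise_share: float, rng) -> np.ndarray:
    """Bin a continuous score into ordinal items.

    Each item's latent value is ``loading * score + e`` with unique normal
    noise sized so that ``noise_share`` of the latent variance is unique;
    the latent is standardized and cut at the item thresholds.  Returns an
    (n, n_items) integer array.  ``noise_share`` 0 gives deterministic
    monotone transforms of the score.
    """
    if not 0.0 <= noise_share < 1.0:
        raise ValueError("noise share must be in [0, 1)")
    s = np.asarray(score, dtype=float)
    var_s = s.var()
    if var_s <= 0:
        raise ValueError("score has zero variance")
    mean_s = s.mean()
    out = np.empty((len(s), len(item_specs)), dtype=float)
    for j, item in enumerate(item_specs):
        lam = item.loading
        common = lam * s
        var_c = lam**2 * var_s
        var_e = noise_share / (1.0 - noise_share) * var_c
        latent = common + (rng.standard_normal(len(s)) * np.sqrt(var_e) if var_e > 0 else 0.0)
        z = (latent - lam * mean_s) / np.sqrt(var_c + var_e)
        out[:, j] = item.first_level + np.searchsorted(item.cuts(), z)
    return out


@dataclass
class MissingnessSpec:
    """Wave-level MAR nonresponse: monotone dropout hazard plus independent
    intermittency, both logistic in baseline age and smoking; wave 0 (the
    entry screening) is always observed."""

    dropout_rate: float | np.ndarray = 0.04     # per-wave hazard (baseline subject)
    intermittent_rate: float | np.ndarray = 0.05
    age_coef: float = 0.3       # logit shift per (age - age_center)/age_scale
    smoking_coef: float = 0.3   # logit shift for smokers
    age_center: float = 42.0
    age_scale: float = 10.0

    def _probs(self, base, age, smoking, T):
        base = np.broadcast_to(np.asarray(base, dtype=float), (T,))
        with np.errstate(divide="ignore"):
            lg = logit(np.clip(base, 0.0, 1.0))
        shift = self.age_coef * (age - self.age_center) / self.age_scale \
            + self.smoking_coef * smoking
        # base 0 or 1 stay exactly 0 or 1 regardless of covariates
        p = expit(lg[None, :] + shift[:, None])
        p = np.where(base[None, :] <= 0.0, 0.0, p)
        p = np.where(base[None, :] >= 1.0, 1.0, p)
        return p

    def observation_matrix(self, age, smoking, T, rng) -> np.ndarray:
        """(n, T) boolean indicator of observed waves."""
        age = np.asarray(age, dtype=float)
        smoking = np.asarray(smoking, dtype=float)
        n = len(age)
        p_drop = self._probs(self.dropout_rate, age, smoking, T)
        p_int = self._probs(self.intermittent_rate, age, smoking, T)
        obs = np.ones((n, T), dtype=bool)
        dropped = np.zeros(n, dtype=bool)
        for t in range(1, T):
            dropped |= rng.random(n) < p_drop[:, t]
            skip = rng.random(n) < p_int[:, t]
            obs[:, t] = ~dropped & ~skip
        return obs


def impose_mar_missingness(panel: PanelDataset, spec: MissingnessSpec, rng) -> PanelDataset:
    """Blank the analysis variables at unobserved waves; returns a new panel."""
    df = panel.data.copy()
    base = panel.baseline()
    smoking = (base["smoking"].astype(str) == "yes").to_numpy(dtype=float)
    age = base["age"].to_numpy(dtype=float)
    obs = spec.observation_matrix(age, smoking, panel.wave_count, rng)
    obs_lookup = {
        (sid, t): obs[i, t]
        for i, sid in enumerate(base["subject_id"])
        for t in range(panel.wave_count)
    }
    keep = np.array(
        [obs_lookup[(sid, w)] for sid, w in zip(df["subject_id"], df["wave"])]
    )
    blank_cols = ANALYSIS_VARS + ["height_cm", "weight_kg"] + [
        c for c in ("pa_score", "hdb_score") if c in df.columns
    ]
    df.loc[~keep, blank_cols] = np.nan
    return PanelDataset(df, wave_count=panel.wave_count, _validated=True)


@dataclass
class StratumConfig:
    gender: str
    weight_status: str
    n: int
    params: ParallelParams
    covariates: study.CovariateMarginals

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("stratum n must be >= 1")


@dataclass
class SimulationConfig:
    strata: list[StratumConfig]
    likert: LikertSpec = field(default_factory=LikertSpec)
    missingness: MissingnessSpec | None = field(default_factory=MissingnessSpec)
    seed: int = 0


def default_params(
    gender: str,
    weight_status: str,
    null_paths: bool = False,
    covariate_gamma: np.ndarray | None = None,
) -> ParallelParams:
    """Generating truth for one stratum from the published reference tables
    plus the documented default scales."""
    ref = study.STRATA[(gender, weight_status)]
    bmi = GrowthParams(
        nu=[ref.bmi.intercept, ref.bmi.slope],
        Psi=[[BMI_INT_SD**2, ref.bmi.cov], [ref.bmi.cov, BMI_SLOPE_SD**2]],
        theta=np.full(T_WAVES, BMI_RESID_SD**2),
        Gamma=covariate_gamma,
    )
    pa = GrowthParams(
        nu=[ref.pa.intercept, ref.pa.slope],
        Psi=[[PCS_INT_SD**2, ref.pa.cov], [ref.pa.cov, PCS_SLOPE_SD**2]],
        theta=np.full(T_WAVES, PCS_RESID_SD**2),
    )
    hdb = GrowthParams(
        nu=[ref.hdb.intercept, ref.hdb.slope],
        Psi=[[PCS_INT_SD**2, ref.hdb.cov], [ref.hdb.cov, PCS_SLOPE_SD**2]],
        theta=np.full(T_WAVES, PCS_RESID_SD**2),
    )
    if null_paths:
        a = b = c = (0.0, 0.0)
    else:
        a = (ref.a[0].est, ref.a[1].est)
        b = (ref.b[0].est, ref.b[1].est)
        c = (ref.c[0].est, ref.c[1].est)
    return ParallelParams(bmi=bmi, pa=pa, hdb=hdb, paths_a=a, paths_b=b, paths_c=c)


def default_config(n_per_stratum: int | None = None, seed: int = 0,
                   missingness: MissingnessSpec | None = None) -> SimulationConfig:
    """All six strata at the published sizes (or a common override)."""
    strata = []
    for (gender, status), ref in study.STRATA.items():
        strata.append(
            StratumConfig(
                gender=gender,
                weight_status=status,
                n=n_per_stratum or ref.n,
                params=default_params(gender, status),
                covariates=ref.covariates,
            )
        )
    if missingness is None:
        missingness = MissingnessSpec()
    return SimulationConfig(strata=strata, missingness=missingness, seed=seed)


def draw_covariates(marg: study.CovariateMarginals, gender: str, n: int, rng) -> pd.DataFrame:
    age = np.clip(rng.normal(marg.age[0], marg.age[1], n), 19.0, 75.0)
    race = np.where(rng.random(n) < marg.race_other, "other", "white")
    education = rng.choice([1, 2, 3, 4], size=n, p=np.asarray(marg.education))
    income = rng.choice([1, 2, 3, 4], size=n, p=np.asarray(marg.income))
    smoking = np.where(rng.random(n) < marg.smoking, "yes", "no")
    alcohol = np.clip(rng.normal(marg.alcohol[0], marg.alcohol[1], n), 0.0, None)
    return pd.DataFrame(
        {
            "gender": gender,
            "age": np.round(age, 1),
            "race": race,
            "education": education,
            "income": income,
            "smoking": smoking,
            "alcohol": np.round(alcohol, 2),
        }
    )


def covariate_design(df: pd.DataFrame) -> np.ndarray:
    """Deviation-coded numeric design used for generator covariate effects."""
    X = np.column_stack(
        [
            df["age"].to_numpy(float),
            (df["race"].astype(str) == "other").astype(float),
            df["education"].to_numpy(float),
            df["income"].to_numpy(float),
            (df["smoking"].astype(str) == "yes").astype(float),
            df["alcohol"].to_numpy(float),
        ]
    )
    return X - X.mean(axis=0)


def simulate_stratum(
    cfg: StratumConfig, likert: LikertSpec, rng, id_prefix: str = ""
) -> pd.DataFrame:
    """One stratum's complete long-format rows (missingness imposed later)."""
    pp = cfg.params
    implied_observed_moments(pp)  # positive-definiteness gate before sampling
    n = cfg.n
    T = T_WAVES
    cov_df = draw_covariates(cfg.covariates, cfg.gender, n, rng)
    X = covariate_design(cov_df)

    _, _, nu_star = factor_moments(pp)
    pred_mean = np.array([pp.pa.nu[0], pp.pa.nu[1], pp.hdb.nu[0], pp.hdb.nu[1]])
    pred = rng.multivariate_normal(pred_mean, pp.pred_cov(), size=n, method="svd")
    if pp.pa.Gamma is not None:
        pred[:, :2] += X @ pp.pa.Gamma.T
    if pp.hdb.Gamma is not None:
        pred[:, 2:] += X @ pp.hdb.Gamma.T
    B = pp.path_matrix()
    zeta = rng.multivariate_normal(np.zeros(2), pp.bmi.Psi, size=n, method="svd")
    bmi_fac = nu_star + pred @ B.T + zeta
    if pp.bmi.Gamma is not None:
        bmi_fac += X @ pp.bmi.Gamma.T

    t = np.arange(T, dtype=float)
    lam = np.vstack([np.ones(T), t])
    mean_b = bmi_fac @ lam
    mean_p = pred[:, :2] @ lam
    mean_h = pred[:, 2:] @ lam
    # wave residuals, jointly across the three processes within a wave
    W = pp.wave_residual_cov
    y_b = np.empty((n, T))
    y_p = np.empty((n, T))
    y_h = np.empty((n, T))
    for ti in range(T):
        C = np.diag([pp.bmi.theta[ti], pp.pa.theta[ti], pp.hdb.theta[ti]]).astype(float)
        if W is not None:
            for a in range(3):
                for b_ in range(a):
                    C[a, b_] = C[b_, a] = W[a, b_]
        eps = rng.multivariate_normal(np.zeros(3), C, size=n, method="svd")
        y_b[:, ti] = mean_b[:, ti] + eps[:, 0]
        y_p[:, ti] = mean_p[:, ti] + eps[:, 1]
        y_h[:, ti] = mean_h[:, ti] + eps[:, 2]
    y_b = np.clip(y_b, 12.0, None)  # physiologic floor for BMI

    height = rng.normal(175.3 if cfg.gender == "male" else 161.8,
                        7.1 if cfg.gender == "male" else 6.5, n)
    height = np.round(np.clip(height, 140.0, 210.0), 1)

    # Likert items from the standardized per-wave behavior scores
    pa_items = np.empty((n, T, 3))
    hdb_items = np.empty((n, T, 3))
    for ti in range(T):
        pa_items[:, ti, :] = discretize_to_likert(
            y_p[:, ti], likert.pa_items, likert.pa_noise_share, rng)
        hdb_items[:, ti, :] = discretize_to_likert(
            y_h[:, ti], likert.hdb_items, likert.hdb_noise_share, rng)

    sid = np.array([f"{id_prefix}{i:06d}" for i in range(n)])
    rows = []
    for ti in range(T):
        weight = np.round(y_b[:, ti] * (height / 100.0) ** 2, 2)
        w = pd.DataFrame(
            {
                "subject_id": sid,
                "wave": ti,
                "height_cm": height,
                # store BMI exactly consistent with the rounded measurements
                "bmi": weight / (height / 100.0) ** 2,
                "weight_kg": weight,
                "pa_score": y_p[:, ti],
                "hdb_score": y_h[:, ti],
            }
        )
        for j, item in enumerate(likert.pa_items):
            w[item.column] = pa_items[:, ti, j]
        for j, item in enumerate(likert.hdb_items):
            w[item.column] = hdb_items[:, ti, j]
        rows.append(pd.concat([cov_df, w], axis=1))
    out = pd.concat(rows, ignore_index=True)
    out = out.sort_values(["subject_id", "wave"], kind="stable").reset_index(drop=True)
    return out


def simulate_parallel_cohort(config: SimulationConfig) -> PanelDataset:
    """Full synthetic cohort across strata; reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    frames = []
    for k, scfg in enumerate(config.strata):
        prefix = f"{scfg.gender[0].upper()}{scfg.weight_status[:2]}-"
        frames.append(simulate_stratum(scfg, config.likert, rng, id_prefix=prefix))
    df = pd.concat(frames, ignore_index=True)
    panel = PanelDataset(df, wave_count=T_WAVES)
    if config.missingness is not None:
        panel = impose_mar_missingness(panel, config.missingness, rng)
    return panel
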