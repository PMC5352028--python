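"""RAM-parameterized structural equation models with ML and FIML estimation.

A model over variables v = (observed, latent) is held as three matrices:

* ``A`` (directed paths, acyclic): factor loadings, covariate regressions,
  structural paths.  ``A[i, j]`` is the path j -> i.
* ``S`` (symmetric): residual variances/covariances and exogenous
  (co)variances.
* ``M`` (means/intercepts).

Implied moments for the observed block follow from
``T = (I - A)^-1``: ``Sigma = F T S T' F'`` and ``mu = F T M`` where ``F``
filters the observed rows.

Estimation maximizes the multivariate-normal likelihood, either from
complete-data sufficient statistics (ML) or casewise over each row's
observed subvector (full-information ML, valid under missing-at-random).
Variance parameters are optimized on the log scale; positive definiteness
of the implied covariance is enforced by an evaluation-time barrier.
Standard errors come from the inverse numerical Hessian at the optimum,
mapped back through the log transform by the delta method.

Exogenous observed covariates are "profiled": their means and covariances
are fixed at the sample values (the likelihood factorizes into p(x) p(y|x),
so this is the joint MLE) but still counted as free parameters when degrees
of freedom are computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "Parameter",
    "RamModel",
    "FitResult",
    "ml_discrepancy",
    "ml_loglik",
    "saturated_loglik_complete",
    "fiml_loglik",
    "saturated_mvn_em",
    "independence_fit",
    "fit_ram",
]

_LN2PI = math.log(2.0 * math.pi)

VARIANCE = "variance"  # optimized as log(value)


@dataclass
class Parameter:
    """One named free (or fixed) parameter and the matrix cells it fills.

    Equality constraints are expressed by registering several cells under
    one name.  ``profiled`` parameters are counted as free for degrees of
    freedom but are held at their set value during optimization.
    """

    name: str
    kind: str  # "variance", "covariance", "mean", "path"
    value: float
    free: bool = True
    profiled: bool = False
    cells: list[tuple[str, int, int]] = field(default_factory=list)


class RamModel:
    """Structural model container; see module docstring for the algebra."""

    def __init__(self, obs_names, latent_names, covariates=()):
        self.obs_names = list(obs_names)
        self.latent_names = list(latent_names)
        self.covariates = list(covariates)
        unknown = set(self.covariates) - set(self.obs_names)
        if unknown:
            raise ValueError(f"covariates not among observed variables: {unknown}")
        self.var_names = self.obs_names + self.latent_names
        self.index = {v: i for i, v in enumerate(self.var_names)}
        if len(self.index) != len(self.var_names):
            raise ValueError("duplicate variable names")
        nv = len(self.var_names)
        self.A0 = np.zeros((nv, nv))
        self.S0 = np.zeros((nv, nv))
        self.M0 = np.zeros(nv)
        self.params: dict[str, Parameter] = {}

    # -- construction ----------------------------------------------------
    def set_fixed(self, matrix: str, row: str, col: str | None, value: float) -> None:
        i = self.index[row]
        if matrix == "M":
            self.M0[i] = value
        elif matrix == "A":
            self.A0[i, self.index[col]] = value
        elif matrix == "S":
            j = self.index[col]
            self.S0[i, j] = self.S0[j, i] = value
        else:
            raise ValueError(matrix)

    def add_param(
        self,
        name: str,
        matrix: str,
        row: str,
        col: str | None,
        value: float,
        kind: str,
        free: bool = True,
        profiled: bool = False,
    ) -> None:
        i = self.index[row]
        j = self.index[col] if col is not None else -1
        if name in self.params:
            p = self.params[name]
            if p.kind != kind:
                raise ValueError(f"parameter {name} registered with two kinds")
        else:
            p = Parameter(name, kind, value, free=free, profiled=profiled)
            self.params[name] = p
        p.cells.append((matrix, i, j))

    # -- parameter bookkeeping -------------------------------------------
    @property
    def free_names(self) -> list[str]:
        """Parameters entering the optimization (free, not profiled)."""
        return [n for n, p in self.params.items() if p.free and not p.profiled]

    @property
    def n_free(self) -> int:
        """Free-parameter count for degrees of freedom (profiled included)."""
        return sum(1 for p in self.params.values() if p.free)

    def set_values(self, values: dict[str, float]) -> None:
        for name, v in values.items():
            self.params[name].value = float(v)

    def get_values(self) -> dict[str, float]:
        return {n: p.value for n, p in self.params.items()}

    def working_start(self) -> np.ndarray:
        w = []
        for n in self.free_names:
            p = self.params[n]
            if p.kind == VARIANCE:
                w.append(math.log(max(p.value, 1e-8)))
            else:
                w.append(p.value)
        return np.array(w)

    def natural_from_working(self, w: np.ndarray) -> np.ndarray:
        out = np.array(w, dtype=float)
        for k, n in enumerate(self.free_names):
            if self.params[n].kind == VARIANCE:
                out[k] = math.exp(min(w[k], 50.0))
        return out

    def matrices(self, working: np.ndarray | None = None):
        """A, S, M with current (or supplied working-scale) free values."""
        A = self.A0.copy()
        S = self.S0.copy()
        M = self.M0.copy()
        if working is not None:
            nat = self.natural_from_working(working)
            values = dict(zip(self.free_names, nat))
        else:
            values = {}
        for name, p in self.params.items():
            v = values.get(name, p.value)
            for mat, i, j in p.cells:
                if mat == "A":
                    A[i, j] = v
                elif mat == "S":
                    S[i, j] = v
                    S[j, i] = v
                else:
                    M[i] = v
        return A, S, M

    def implied_moments(self, working: np.ndarray | None = None):
        """Model-implied (Sigma, mu) for the observed variables."""
        A, S, M = self.matrices(working)
        nv = len(self.var_names)
        T = np.linalg.solve(np.eye(nv) - A, np.eye(nv))
        full = T @ S @ T.T
        mu = T @ M
        p = len(self.obs_names)
        return full[:p, :p], mu[:p]

    def check_acyclic(self) -> bool:
        adj = (self.A0 != 0).astype(float)
        for p in self.params.values():
            for mat, i, j in p.cells:
                if mat == "A":
                    adj[i, j] = 1.0
        power = adj.copy()
        for _ in range(len(self.var_names)):
            if not power.any():
                return True
            power = (power @ adj != 0).astype(float)
        return False


# -- likelihood pieces ----------------------------------------------------

def ml_discrepancy(S, ybar, Sigma, mu):
    """The ML fit function F_ML >= 0, zero iff (Sigma, mu) == (S, ybar)."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    L = np.linalg.cholesky(Sigma)
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(L)))
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("sample covariance not positive definite")
    Sigma_inv = np.linalg.inv(Sigma)
    d = np.asarray(ybar, dtype=float) - np.asarray(mu, dtype=float)
    return float(
        logdet_sigma - logdet_s + np.trace(S @ Sigma_inv) - p + d @ Sigma_inv @ d
    )


def ml_loglik(S, ybar, n, Sigma, mu):
    """Multivariate-normal loglik from sufficient statistics (S uses 1/n)."""
    p = S.shape[0]
    L = np.linalg.cholesky(Sigma)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Sigma_inv = np.linalg.inv(Sigma)
    d = np.asarray(ybar) - np.asarray(mu)
    return -0.5 * n * (p * _LN2PI + logdet + np.trace(S @ Sigma_inv) + d @ Sigma_inv @ d)


def saturated_loglik_complete(S, n):
    """Loglik of the saturated model (Sigma=S, mu=ybar) for complete data."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise np.linalg.LinAlgError("sample covariance not positive definite")
    return -0.5 * n * (p * _LN2PI + logdet + p)


def _pattern_groups(Y: np.ndarray):
    """Group row indices by missingness pattern; complete rows first."""
    obs = ~np.isnan(Y)
    # encode each pattern as bytes for grouping
    keys = np.ascontiguousarray(obs).view(
        np.dtype((np.void, obs.dtype.itemsize * obs.shape[1]))
    ).ravel()
    order = np.argsort(keys, kind="stable")
    groups = []
    start = 0
    for k in range(1, len(order) + 1):
        if k == len(order) or keys[order[k]] != keys[order[start]]:
            rows = order[start:k]
            groups.append((obs[rows[0]], rows))
            start = k
    return groups


def fiml_loglik(Y, Sigma, mu, return_skipped=False):
    """Casewise multivariate-normal loglik over observed subvectors.

    Rows with no observed variable are skipped (counted, with a warning the
    first time).  Missingness patterns are grouped so the per-pattern
    Cholesky is computed once.
    """
    Y = np.asarray(Y, dtype=float)
    total = 0.0
    skipped = 0
    for pat, rows in _pattern_groups(Y):
        k = int(pat.sum())
        if k == 0:
            skipped += len(rows)
            continue
        sub = Y[np.ix_(rows, np.flatnonzero(pat))]
        Sg = Sigma[np.ix_(pat, pat)]
        mg = mu[pat]
        L = np.linalg.cholesky(Sg)
        z = np.linalg.solve(L, (sub - mg).T)
        quad = np.sum(z * z, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        total += -0.5 * (len(rows) * (k * _LN2PI + logdet) + quad.sum())
    if skipped:
        warnings.warn(f"skipped {skipped} rows with no observed variables")
    if return_skipped:
        return total, skipped
    return total


def saturated_mvn_em(Y, max_iter=500, tol=1e-7):
    """Saturated (mu, Sigma) MLE under missing-at-random via EM.

    Returns (mu, Sigma, loglik).  Standard EM for the multivariate normal:
    the E step fills conditional means and adds conditional covariances of
    the missing blocks; the M step recomputes moments.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    mu = np.nanmean(Y, axis=0)
    dev = np.where(np.isnan(Y), 0.0, Y - mu)
    Sigma = dev.T @ dev / n + np.eye(p) * 1e-3
    groups = _pattern_groups(Y)
    last = -np.inf
    for _ in range(max_iter):
        sum_y = np.zeros(p)
        sum_yy = np.zeros((p, p))
        n_used = 0
        for pat, rows in groups:
            if not pat.any():
                continue
            o = np.flatnonzero(pat)
            m = np.flatnonzero(~pat)
            sub = Y[np.ix_(rows, o)]
            n_g = len(rows)
            n_used += n_g
            filled = np.empty((n_g, p))
            filled[:, o] = sub
            if len(m):
                Soo = Sigma[np.ix_(o, o)]
                Smo = Sigma[np.ix_(m, o)]
                coefs = np.linalg.solve(Soo, Smo.T).T  # m x o
                cond_mean = mu[m] + (sub - mu[o]) @ coefs.T
                filled[:, m] = cond_mean
                cond_cov = Sigma[np.ix_(m, m)] - coefs @ Smo.T
                sum_yy[np.ix_(m, m)] += n_g * cond_cov
            sum_y += filled.sum(axis=0)
            sum_yy += filled.T @ filled
        mu = sum_y / n_used
        Sigma = sum_yy / n_used - np.outer(mu, mu)
        Sigma = (Sigma + Sigma.T) / 2
        ll = fiml_loglik(Y, Sigma, mu)
        if abs(ll - last) < tol * (1 + abs(ll)):
            last = ll
            break
        last = ll
    return mu, Sigma, last


def independence_fit(Y):
    """Independence (baseline) model: free means and variances, zero
    covariances.  The likelihood factorizes per variable, so the MLE is the
    per-variable observed-case mean/variance even with missing data.

    Returns (loglik, n_free_params).
    """
    Y = np.asarray(Y, dtype=float)
    ll = 0.0
    p = Y.shape[1]
    for j in range(p):
        col = Y[:, j]
        col = col[~np.isnan(col)]
        nj = len(col)
        if nj == 0:
            continue
        var = max(col.var(), 1e-12)
        ll += -0.5 * nj * (_LN2PI + math.log(var) + 1.0)
    return ll, 2 * p


# -- fitting ---------------------------------------------------------------

@dataclass
class FitResult:
    """Point estimates, uncertainty and likelihood summaries for one fit."""

    model: RamModel
    estimates: dict[str, float]
    se: dict[str, float] | None
    loglik: float
    loglik_saturated: float
    chi2: float
    df: int
    n: int
    n_effective: int
    converged: bool
    grad_norm: float
    estimator: str
    n_dropped: int = 0
    vcov: pd.DataFrame | None = None
    indices: object = None  # FitIndices, filled by fitstats
    data_hash: int | None = None
    used_data: np.ndarray | None = None  # rows actually entering the likelihood

    def param_table(self) -> pd.DataFrame:
        rows = []
        for name in self.model.free_names:
            est = self.estimates[name]
            se = self.se.get(name) if self.se else np.nan
            se = np.nan if se is None else se
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "se": se,
                    "ci_lo": est - 1.959963984540054 * se,
                    "ci_hi": est + 1.959963984540054 * se,
                }
            )
        return pd.DataFrame(rows)


_BARRIER = 1e12


def _suffstats(arr: np.ndarray):
    """Per-missingness-pattern sufficient statistics.

    Returns a list of (observed-index array, n_g, mean_g, C_g) with C_g the
    within-pattern MLE covariance; the FIML loglik is then
    sum_g -n_g/2 [k ln 2pi + ln|Sigma_oo| + tr((C_g + d_g d_g') Sigma_oo^-1)]
    with d_g = mean_g - mu_oo, which equals the casewise sum exactly.
    """
    out = []
    for pat, rows in _pattern_groups(arr):
        idx = np.flatnonzero(pat)
        if len(idx) == 0:
            continue
        sub = arr[np.ix_(rows, idx)]
        ybar = sub.mean(axis=0)
        dev = sub - ybar
        out.append((idx, len(sub), ybar, dev.T @ dev / len(sub)))
    return out


def loglik_and_score(model: RamModel, w: np.ndarray, stats):
    """Loglik and its analytic gradient on the working scale.

    The chain rule runs through dl = tr(G dSigma) + g_mu' dmu, where G and
    g_mu accumulate the standard multivariate-normal derivatives per
    missingness pattern; structural derivatives use the RAM identities
    d(TST')/dA_ij = T[:,i] V[j,:] + V[:,j] T[:,i]' (V = TST'),
    dSigma/dS_ij = W[:,i] W[:,j]' + (transpose), dmu/dM_i = W[:,i],
    with W the observed rows of T = (I-A)^-1.
    """
    A, S, M = model.matrices(w)
    nv = len(model.var_names)
    p = len(model.obs_names)
    T = np.linalg.solve(np.eye(nv) - A, np.eye(nv))
    V = T @ S @ T.T
    TM = T @ M
    W = T[:p, :]
    Sigma = V[:p, :p]
    mu = TM[:p]
    np.linalg.cholesky(Sigma)  # raises LinAlgError -> barrier upstream

    G = np.zeros((p, p))
    gmu = np.zeros(p)
    ll = 0.0
    for idx, ng, ybar, C in stats:
        k = len(idx)
        Soo = Sigma[np.ix_(idx, idx)]
        L = np.linalg.cholesky(Soo)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        inv = np.linalg.inv(Soo)
        d = ybar - mu[idx]
        aug = C + np.outer(d, d)
        ll += -0.5 * ng * (k * _LN2PI + logdet + np.sum(inv * aug))
        G[np.ix_(idx, idx)] += -0.5 * ng * (inv - inv @ aug @ inv)
        gmu[idx] += ng * (inv @ d)

    WtG = W.T @ G                 # nv x p
    WtGW = WtG @ W                # nv x nv, entry (i,j) = W[:,i]' G W[:,j]
    WtGVp = WtG @ V[:p, :]        # nv x nv, entry (i,j) = W[:,i]' G V[:p,j]
    gmuW = gmu @ W                # nv, entry i = g_mu' W[:,i]

    names = model.free_names
    grad = np.zeros(len(names))
    for k_i, name in enumerate(names):
        g = 0.0
        for mat, i, j in model.params[name].cells:
            if mat == "S":
                g += WtGW[i, i] if i == j else 2.0 * WtGW[i, j]
            elif mat == "A":
                g += 2.0 * WtGVp[i, j] + gmuW[i] * TM[j]
            else:  # M
                g += gmuW[i]
        grad[k_i] = g
    # chain to working scale (variances are exp-transformed)
    for k_i, name in enumerate(names):
        if model.params[name].kind == VARIANCE:
            grad[k_i] *= math.exp(min(w[k_i], 50.0))
    return ll, grad


def _profile_covariate_moments(model: RamModel, Y: pd.DataFrame) -> None:
    """Fix covariate means/covariances at sample values (profiled params)."""
    covs = model.covariates
    if not covs:
        return
    X = Y[covs].to_numpy(dtype=float)
    ok = ~np.isnan(X).any(axis=1)
    X = X[ok]
    xbar = X.mean(axis=0)
    C = np.cov(X, rowvar=False, ddof=0).reshape(len(covs), len(covs))
    for i, c in enumerate(covs):
        model.set_values({f"x_mean_{c}": xbar[i], f"x_var_{c}": max(C[i, i], 1e-10)})
        for j in range(i):
            model.set_values({f"x_cov_{covs[j]}_{c}": C[j, i]})


def fit_ram(
    model: RamModel,
    data: pd.DataFrame,
    estimator: str = "ml",
    start: dict[str, float] | None = None,
    compute_se: bool = True,
    gtol: float = 1e-4,
    maxiter: int = 3000,
    hessian_rel_step: float = 1e-4,
) -> FitResult:
    """Fit a RAM model to a data frame whose columns cover the observed
    variables.

    estimator 'ml' uses listwise-complete rows and sufficient statistics;
    'fiml' uses each row's observed subvector (rows missing a covariate are
    dropped first, since covariates are treated as fixed regressors).
    Non-convergence is reported in the result, never raised.
    """
    if estimator not in ("ml", "fiml"):
        raise ValueError("estimator must be 'ml' or 'fiml'")
    missing_cols = [c for c in model.obs_names if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks model variables: {missing_cols}")
    Y = data[model.obs_names].copy()
    n_input = len(Y)

    n_dropped = 0
    if estimator == "fiml" and model.covariates:
        ok = ~Y[model.covariates].isna().any(axis=1)
        n_dropped = int((~ok).sum())
        Y = Y[ok]
    if estimator == "ml":
        ok = ~Y.isna().any(axis=1)
        n_dropped = int((~ok).sum())
        Y = Y[ok]
    arr = Y.to_numpy(dtype=float)
    n = len(arr)
    p = len(model.obs_names)
    if n < p + 1:
        raise ValueError(f"too few usable rows ({n}) for {p} observed variables")

    _profile_covariate_moments(model, Y)
    if start:
        model.set_values(start)

    if estimator == "ml":
        S = np.cov(arr, rowvar=False, ddof=0)
        ll_sat = saturated_loglik_complete(S, n)
    stats = _suffstats(arr)
    kfree = len(model.free_names)

    def neg_ll_grad(w):
        try:
            ll, g = loglik_and_score(model, w, stats)
            return -ll / n, -g / n
        except (np.linalg.LinAlgError, FloatingPointError):
            return _BARRIER, np.zeros(kfree)

    w0 = model.working_start()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            neg_ll_grad,
            w0,
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": maxiter, "maxfun": 10 * maxiter, "ftol": 1e-14,
                     "gtol": gtol / 10},
        )
    w_hat = res.x
    f_hat = res.fun
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    if np.isfinite(f_hat) and grad_norm >= gtol:
        # quasi-Newton can stall on flat, ill-conditioned surfaces; polish
        # with damped Newton steps using a finite-difference Hessian of the
        # analytic gradient
        w_hat, f_hat, grad_norm = _newton_polish(
            neg_ll_grad, w_hat, gtol, hessian_rel_step)
    converged = bool(np.isfinite(f_hat)) and grad_norm < gtol
    loglik = -f_hat * n

    nat = model.natural_from_working(w_hat)
    model.set_values(dict(zip(model.free_names, nat)))
    estimates = model.get_values()

    if estimator == "fiml":
        if np.isnan(arr).any():
            _, _, ll_sat = saturated_mvn_em(arr)
        else:
            S_c = np.cov(arr, rowvar=False, ddof=0)
            ll_sat = saturated_loglik_complete(S_c, n)

    chi2 = max(2.0 * (ll_sat - loglik), 0.0)
    if 2.0 * (ll_sat - loglik) < -1e-4 * (1 + abs(ll_sat)):
        warnings.warn("model loglik exceeds saturated loglik; optimization suspect")
    df = p * (p + 3) // 2 - model.n_free

    se = None
    vcov = None
    if compute_se and converged:
        se, vcov = _hessian_se(model, neg_ll_grad, w_hat, n, hessian_rel_step)

    return FitResult(
        model=model,
        estimates=estimates,
        se=se,
        loglik=loglik,
        loglik_saturated=ll_sat,
        chi2=chi2,
        df=df,
        n=n_input,
        n_effective=n,
        converged=converged,
        grad_norm=grad_norm,
        estimator=estimator,
        n_dropped=n_dropped,
        vcov=vcov,
        data_hash=int(pd.util.hash_pandas_object(Y).sum()),
        used_data=arr,
    )


def _grad_hessian(neg_ll_grad, w, rel_step):
    """Numerical Hessian by central differences of the analytic gradient."""
    k = len(w)
    steps = rel_step * np.maximum(np.abs(w), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = steps[i]
        _, gp = neg_ll_grad(w + e)
        _, gm = neg_ll_grad(w - e)
        H[:, i] = (gp - gm) / (2 * steps[i])
    return (H + H.T) / 2


def _newton_polish(neg_ll_grad, w, gtol, rel_step, max_steps=25):
    """Levenberg-damped Newton refinement until the gradient norm drops
    below ``gtol`` (or progress stalls)."""
    f, g = neg_ll_grad(w)
    ridge = 1e-8
    best_gnorm = np.inf
    stalled = 0
    for _ in range(max_steps):
        gnorm = float(np.max(np.abs(g)))
        if gnorm < gtol or not np.isfinite(f):
            break
        if gnorm < 0.9 * best_gnorm:
            best_gnorm = gnorm
            stalled = 0
        else:
            stalled += 1
            if stalled >= 3:
                break
        H = _grad_hessian(neg_ll_grad, w, rel_step)
        improved = False
        for _ in range(12):
            try:
                step = np.linalg.solve(H + ridge * np.eye(len(w)), -g)
            except np.linalg.LinAlgError:
                ridge *= 10
                continue
            f_new, g_new = neg_ll_grad(w + step)
            if np.isfinite(f_new) and f_new <= f + 1e-12:
                w = w + step
                f, g = f_new, g_new
                ridge = max(ridge / 10, 1e-10)
                improved = True
                break
            ridge *= 10
        if not improved:
            break
    return w, f, float(np.max(np.abs(g)))


def _hessian_se(model, neg_ll_grad, w_hat, n, rel_step):
    """SEs from the inverse numerical Hessian at the optimum, built by
    central differences of the analytic gradient of the per-observation
    negative loglik, then delta-mapped through exp for variances.
    """
    k = len(w_hat)
    H = _grad_hessian(neg_ll_grad, w_hat, rel_step)
    try:
        cov_w = np.linalg.inv(H * n)
    except np.linalg.LinAlgError:
        cov_w = np.linalg.pinv(H * n)
    # delta method: d(natural)/d(working) is exp(w) for variances, 1 otherwise
    jac = np.ones(k)
    for idx, name in enumerate(model.free_names):
        if model.params[name].kind == VARIANCE:
            jac[idx] = math.exp(w_hat[idx])
    cov_nat = cov_w * np.outer(jac, jac)
    diag = np.diag(cov_nat)
    se_vec = np.sqrt(np.where(diag > 0, diag, np.nan))
    names = model.free_names
    se = dict(zip(names, se_vec))
    vcov = pd.DataFrame(cov_nat, index=names, columns=names)
    return se, vcov
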