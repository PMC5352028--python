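"""Standardized principal-component scores for the PA and HDB item batteries.

For each annual wave, a PCA of the three-item correlation matrix is fitted
on complete cases; the first component (retained under the eigenvalue > 1
rule) defines the composite.  Scores are the first-component projection of
the standardized items, z-scored either within each wave (default) or over
the pooled sample, and sign-oriented so that higher scores mean more of
the behavior (positive loading sum, tie broken by the first item).
Subjects missing any item at a wave get a missing score there — items are
never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import HDB_ITEMS, PA_ITEMS, PanelDataset

__all__ = [
    "PcaWaveResult",
    "fit_pca_wave",
    "retain_components",
    "compute_pcs",
    "PCSScorer",
    "score_panel",
]


@dataclass
class PcaWaveResult:
    """Eigenstructure of one wave's 3-item correlation matrix."""

    loadings: np.ndarray       # (3, 3), column k = unit-norm loadings of PC k
    eigenvalues: np.ndarray    # descending; sums to 3 (correlation PCA)
    variance_share: np.ndarray  # eigenvalue / 3
    n_used: int
    item_means: np.ndarray
    item_sds: np.ndarray


def fit_pca_wave(items: np.ndarray, standardize: bool = True) -> PcaWaveResult:
    """PCA of a (n, 3) item matrix on complete cases.

    With ``standardize`` (the default) the correlation matrix is
    decomposed, so the three items' different Likert ranges do not weight
    the composite.  Raises on fewer than 3 complete rows or a zero-variance
    item.
    """
    X = np.asarray(items, dtype=float)
    ok = ~np.isnan(X).any(axis=1)
    X = X[ok]
    if len(X) < 3:
        raise ValueError(f"need >= 3 complete rows for PCA, got {len(X)}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(sds == 0)
    if len(zero):
        raise ValueError(f"zero-variance item at column {zero[0]}")
    if standardize:
        Z = (X - means) / sds
        C = Z.T @ Z / len(Z)
    else:
        C = np.cov(X, rowvar=False, ddof=0)
        sds = np.ones(3)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    # deterministic sign: positive loading sum, tie broken by first item
    for k in range(V.shape[1]):
        s = V[:, k].sum()
        if s < 0 or (s == 0 and V[0, k] < 0):
            V[:, k] = -V[:, k]
    total = C.trace()
    return PcaWaveResult(
        loadings=V,
        eigenvalues=w,
        variance_share=w / total,
        n_used=len(X),
        item_means=means,
        item_sds=sds,
    )


def retain_components(eigenvalues) -> int:
    """Count of components with eigenvalue strictly greater than 1.

    Warns when the count differs from 1 (a single retained component is the
    expected structure for these batteries).
    """
    w = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(w) > 1e-12):
        raise ValueError("eigenvalues must be in descending order")
    k = int((w > 1.0).sum())
    if k != 1:
        warnings.warn(f"eigenvalue>1 rule retains {k} components, not 1")
    return k


def compute_pcs(
    items_by_wave: dict[int, np.ndarray],
    wave_results: dict[int, PcaWaveResult],
    standardization_scope: str = "per_wave",
) -> dict[int, np.ndarray]:
    """First-component scores per wave, z-scored within the declared scope.

    ``items_by_wave[t]`` is the (n, 3) item matrix for wave t (NaN where an
    item is missing; any missing item gives a missing score).  Returns a
    matching dict of score vectors with mean 0 / SD 1 over the non-missing
    scores in scope.
    """
    if standardization_scope not in ("per_wave", "pooled"):
        raise ValueError("standardization_scope must be 'per_wave' or 'pooled'")
    raw: dict[int, np.ndarray] = {}
    for t, X in items_by_wave.items():
        X = np.asarray(X, dtype=float)
        r = wave_results[t]
        Z = (X - r.item_means) / r.item_sds
        s = Z @ r.loadings[:, 0]
        raw[t] = s  # NaN propagates from missing items
    if standardization_scope == "per_wave":
        out = {}
        for t, s in raw.items():
            m = np.nanmean(s)
            sd = np.nanstd(s, ddof=0)
            out[t] = (s - m) / sd
        return out
    allv = np.concatenate(list(raw.values()))
    m = np.nanmean(allv)
    sd = np.nanstd(allv, ddof=0)
    return {t: (s - m) / sd for t, s in raw.items()}


class PCSScorer(BaseEstimator, TransformerMixin):
    """Per-wave PCA composite scorer with a scikit-learn transformer surface.

    Operates on a long-format panel frame; ``transform`` appends a
    standardized composite column per battery.

    Parameters
    ----------
    batteries : dict mapping score column name -> list of item columns
        Default: ``{'pcs_pa': PA items, 'pcs_hdb': HDB items}``.
    scope : {'per_wave', 'pooled'}
        Standardization scope of the scores.
    """

    def __init__(self, batteries=None, scope: str = "per_wave", wave_count: int = 7):
        self.batteries = batteries
        self.scope = scope
        self.wave_count = wave_count

    def _batteries(self):
        return self.batteries or {"pcs_pa": PA_ITEMS, "pcs_hdb": HDB_ITEMS}

    def fit(self, X: pd.DataFrame, y=None):
        self.wave_results_ = {}
        self.report_ = []
        for score_col, items in self._batteries().items():
            per_wave = {}
            for t in range(self.wave_count):
                sub = X.loc[X["wave"] == t, items].to_numpy(dtype=float)
                try:
                    r = fit_pca_wave(sub)
                except ValueError as err:
                    raise ValueError(f"{score_col}, wave {t}: {err}") from err
                retain_components(r.eigenvalues)
                per_wave[t] = r
                self.report_.append(
                    {
                        "battery": score_col,
                        "wave": t,
                        "n_used": r.n_used,
                        "eig1": r.eigenvalues[0],
                        "eig2": r.eigenvalues[1],
                        "eig3": r.eigenvalues[2],
                        "pc1_share": r.variance_share[0],
                    }
                )
            self.wave_results_[score_col] = per_wave
        self.report_ = pd.DataFrame(self.report_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X.copy()
        for score_col, items in self._batteries().items():
            items_by_wave = {}
            index_by_wave = {}
            for t in range(self.wave_count):
                mask = X["wave"] == t
                items_by_wave[t] = X.loc[mask, items].to_numpy(dtype=float)
                index_by_wave[t] = X.index[mask]
            scores = compute_pcs(items_by_wave, self.wave_results_[score_col], self.scope)
            col = pd.Series(np.nan, index=X.index)
            for t, s in scores.items():
                col.loc[index_by_wave[t]] = s
            X[score_col] = col
        return X


def score_panel(panel: PanelDataset, scope: str = "per_wave"):
    """Convenience wrapper: fit the scorer on a panel and return
    (scored long frame, per-wave PCA report)."""
    scorer = PCSScorer(scope=scope, wave_count=panel.wave_count)
    scored = scorer.fit(panel.data).transform(panel.data)
    return scored, scorer.report_
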