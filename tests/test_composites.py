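"""PCA composites: eigenstructure oracles, retention rule, scoring
contracts (standardization, orientation, missingness propagation)."""

import numpy as np
import pytest

from growthsem.composites import (
    PCSScorer,
    compute_pcs,
    fit_pca_wave,
    retain_components,
)
from conftest import make_panel_frame


def brute_force_eigenvalues(C):
    """Roots of the characteristic polynomial of a 3x3 symmetric matrix —
    an eigensolver-independent oracle."""
    c2 = -np.trace(C)
    c1 = (np.trace(C) ** 2 - np.trace(C @ C)) / 2
    c0 = -np.linalg.det(C)
    roots = np.roots([1.0, c2, c1, c0])
    return np.sort(roots.real)[::-1]


class TestFitPcaWave:
    def test_uncorrelated_items_near_unit_eigenvalues(self, rng):
        X = rng.normal(size=(20_000, 3))
        r = fit_pca_wave(X)
        assert np.allclose(r.eigenvalues, 1.0, atol=0.05)
        assert np.allclose(r.variance_share, 1 / 3, atol=0.02)

    def test_perfectly_correlated_items(self, rng):
        base = rng.normal(size=500)
        X = np.column_stack([base, 2 * base + 1, -0.5 * base])
        r = fit_pca_wave(X)
        assert r.eigenvalues[0] == pytest.approx(3.0, abs=1e-10)
        assert r.variance_share[0] == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalues_match_characteristic_polynomial(self, rng):
        for _ in range(50):
            X = rng.normal(size=(20, 3)) @ rng.normal(size=(3, 3))
            r = fit_pca_wave(X)
            Z = (X - X.mean(0)) / X.std(0)
            C = Z.T @ Z / len(Z)
            assert np.allclose(r.eigenvalues, brute_force_eigenvalues(C), atol=1e-8)
            assert np.allclose(np.linalg.norm(r.loadings, axis=0), 1.0, atol=1e-10)
            assert r.eigenvalues.sum() == pytest.approx(3.0, abs=1e-8)

    def test_too_few_rows_and_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="complete rows"):
            fit_pca_wave(np.ones((2, 3)))
        X = np.random.default_rng(0).normal(size=(10, 3))
        X[:, 1] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pca_wave(X)

    def test_complete_case_restriction(self, rng):
        X = rng.normal(size=(50, 3))
        Xm = X.copy()
        Xm[:10, 0] = np.nan
        r = fit_pca_wave(Xm)
        assert r.n_used == 40


class TestRetention:
    @pytest.mark.parametrize(
        "eigs, expected", [((3.0, 0.0, 0.0), 1), ((1.8, 0.7, 0.5), 1),
                           ((2.0, 1.5, 0.1), 2)]
    )
    def test_rule(self, eigs, expected, recwarn):
        assert retain_components(eigs) == expected

    def test_boundary_is_strict_with_warning(self):
        with pytest.warns(UserWarning, match="retains 0"):
            assert retain_components((1.0, 1.0, 1.0)) == 0


class TestScores:
    def _wave_data(self, rng, n=200):
        f = rng.normal(size=n)
        X = np.column_stack([f + 0.3 * rng.normal(size=n) for _ in range(3)])
        return X

    def test_standardization_and_formula_oracle(self, rng):
        X = self._wave_data(rng)
        r = fit_pca_wave(X)
        scores = compute_pcs({0: X}, {0: r}, "per_wave")[0]
        assert np.nanmean(scores) == pytest.approx(0.0, abs=1e-9)
        assert np.nanstd(scores) == pytest.approx(1.0, abs=1e-9)
        # brute-force: standardized items times loadings, then z-scored
        raw = ((X - r.item_means) / r.item_sds) @ r.loadings[:, 0]
        expect = (raw - raw.mean()) / raw.std()
        assert np.allclose(scores, expect, atol=1e-10)

    def test_pooled_scope(self, rng):
        waves = {t: self._wave_data(rng) for t in range(3)}
        results = {t: fit_pca_wave(X) for t, X in waves.items()}
        scores = compute_pcs(waves, results, "pooled")
        allv = np.concatenate(list(scores.values()))
        assert np.nanmean(allv) == pytest.approx(0.0, abs=1e-9)
        assert np.nanstd(allv) == pytest.approx(1.0, abs=1e-9)

    def test_missing_item_gives_missing_score_never_imputed(self, rng):
        X = self._wave_data(rng)
        X[5, 1] = np.nan
        r = fit_pca_wave(X)
        scores = compute_pcs({0: X}, {0: r}, "per_wave")[0]
        assert np.isnan(scores[5])
        assert np.isfinite(np.delete(scores, 5)).all()

    def test_orientation_max_items_score_highest(self, rng):
        X = self._wave_data(rng, n=100)
        X[0] = X.max(axis=0) + 1.0
        r = fit_pca_wave(X)
        scores = compute_pcs({0: X}, {0: r}, "per_wave")[0]
        assert scores[0] == scores.max()

    def test_sign_stable_under_item_permutation(self, rng):
        X = self._wave_data(rng)
        perm = [2, 0, 1]
        r1 = fit_pca_wave(X)
        r2 = fit_pca_wave(X[:, perm])
        s1 = compute_pcs({0: X}, {0: r1}, "per_wave")[0]
        s2 = compute_pcs({0: X[:, perm]}, {0: r2}, "per_wave")[0]
        assert np.allclose(s1, s2, atol=1e-9)

    def test_equicorrelated_share_closed_form(self, rng):
        # common-factor share s implies PC1 share -> s + (1-s)/3
        s = 0.6
        n = 60_000
        f = rng.normal(size=n)
        X = np.column_stack(
            [np.sqrt(s) * f + np.sqrt(1 - s) * rng.normal(size=n) for _ in range(3)]
        )
        r = fit_pca_wave(X)
        assert r.variance_share[0] == pytest.approx(s + (1 - s) / 3, abs=0.01)


class TestScorer:
    def test_transform_appends_standardized_columns(self):
        df = make_panel_frame(n_subjects=40, seed=5)
        scorer = PCSScorer().fit(df)
        out = scorer.transform(df)
        for col in ("pcs_pa", "pcs_hdb"):
            assert col in out
            for t in range(7):
                sub = out.loc[out.wave == t, col]
                assert sub.mean() == pytest.approx(0.0, abs=1e-9)
                assert sub.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert len(scorer.report_) == 14  # 2 batteries x 7 waves

    def test_subject_relabeling_invariance(self):
        df = make_panel_frame(n_subjects=40, seed=5)
        out1 = PCSScorer().fit(df).transform(df)
        df2 = df.copy()
        df2["subject_id"] = df2["subject_id"].map(lambda s: "x" + s)
        out2 = PCSScorer().fit(df2).transform(df2)
        assert np.allclose(out1["pcs_pa"], out2["pcs_pa"], atol=1e-12)
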