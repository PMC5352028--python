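"""Baseline-table statistics: one-way ANOVA with Tukey HSD, the chi-square
test of independence for nominal variables, and the Mantel-Haenszel
chi-square of linear association for ordinal ones."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ContingencyTable",
    "oneway_anova_tukey",
    "chi2_independence",
    "mh_linear_association",
    "baseline_table",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list
    col_labels: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative cell counts")
        if self.counts.sum() < 1:
            raise ValueError("empty table")

    @classmethod
    def from_series(cls, rows: pd.Series, cols: pd.Series,
                    row_order=None, col_order=None) -> "ContingencyTable":
        tab = pd.crosstab(rows, cols)
        if row_order is not None:
            tab = tab.reindex(index=row_order, fill_value=0)
        if col_order is not None:
            tab = tab.reindex(columns=col_order, fill_value=0)
        return cls(tab.to_numpy(), list(tab.index), list(tab.columns))


@dataclass
class AnovaResult:
    f: float
    p: float
    significant_pairs: set  # frozenset pairs of group labels, family alpha 0.05


def oneway_anova_tukey(groups: dict) -> AnovaResult:
    """Classical one-way ANOVA F test plus Tukey HSD pairwise flags.

    ``groups`` maps label -> 1d sample; each group needs n >= 2.
    """
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    samples = [s[~np.isnan(s)] for s in samples]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with n >= 2 each")
    f, p = stats.f_oneway(*samples)
    values = np.concatenate(samples)
    codes = np.concatenate([[g] * len(s) for g, s in zip(labels, samples)])
    sig = set()
    if np.ptp(values) > 0:
        tk = pairwise_tukeyhsd(values, codes, alpha=0.05)
        for (g1, g2), rej in zip(
            [(tk.groupsunique[i], tk.groupsunique[j]) for i, j in
             zip(*np.triu_indices(len(tk.groupsunique), 1))],
            tk.reject,
        ):
            if rej:
                sig.add(frozenset((g1, g2)))
    return AnovaResult(f=float(f), p=float(p), significant_pairs=sig)


def chi2_independence(table: ContingencyTable):
    """Pearson chi-square of independence; returns (statistic, df, p)."""
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def mh_linear_association(table: ContingencyTable, row_scores=None, col_scores=None):
    """Mantel-Haenszel chi-square of linear association, M^2 = (N-1) r^2.

    ``r`` is the Pearson correlation between the scored row and column
    variables over the N individuals in the table (default integer scores
    1..k).  Returns (M2, df=1, p).
    """
    counts = table.counts
    r_sc = np.arange(1, counts.shape[0] + 1, dtype=float) if row_scores is None \
        else np.asarray(row_scores, dtype=float)
    c_sc = np.arange(1, counts.shape[1] + 1, dtype=float) if col_scores is None \
        else np.asarray(col_scores, dtype=float)
    if np.any(np.diff(r_sc) <= 0) or np.any(np.diff(c_sc) <= 0):
        raise ValueError("scores must be strictly increasing")
    N = counts.sum()
    if N < 2:
        raise ValueError("need N >= 2")
    pr = counts.sum(axis=1) / N
    pc = counts.sum(axis=0) / N
    mr = r_sc @ pr
    mc = c_sc @ pc
    vr = ((r_sc - mr) ** 2) @ pr
    vc = ((c_sc - mc) ** 2) @ pc
    if vr <= 0 or vc <= 0:
        raise ValueError("zero variance in a scored margin")
    cov = (r_sc - mr) @ (counts / N) @ (c_sc - mc)
    r = cov / np.sqrt(vr * vc)
    m2 = float((N - 1) * r**2)
    return m2, 1, float(stats.chi2.sf(m2, 1))


def baseline_table(baseline: pd.DataFrame, group_col: str = "weight_status",
                   group_order=("normal", "overweight", "obese")) -> pd.DataFrame:
    """Descriptive comparison of baseline variables across weight status.

    Continuous variables get mean (SD) per group with the ANOVA/Tukey
    battery; categorical ones get n (%) with the independence chi-square,
    or the linear-association trend test when the variable is ordinal.
    """
    cont = [c for c in ("age", "alcohol") if c in baseline.columns]
    nominal = [c for c in ("race", "smoking") if c in baseline.columns]
    ordinal = [c for c in ("education", "income") if c in baseline.columns]
    groups_present = [g for g in group_order if (baseline[group_col] == g).any()]
    rows = []
    for var in cont:
        groups = {
            g: baseline.loc[baseline[group_col] == g, var].to_numpy(dtype=float)
            for g in groups_present
        }
        res = oneway_anova_tukey(groups)
        row = {"variable": var, "test": "anova", "statistic": res.f, "p": res.p,
               "significant_pairs": ";".join(
                   "|".join(sorted(pair)) for pair in sorted(
                       res.significant_pairs, key=lambda s: sorted(s)))}
        for g in groups_present:
            row[g] = f"{np.nanmean(groups[g]):.2f} ({np.nanstd(groups[g], ddof=1):.2f})"
        rows.append(row)
    for var, ordinal_flag in [(v, False) for v in nominal] + [(v, True) for v in ordinal]:
        tab = ContingencyTable.from_series(
            baseline[var], baseline[group_col], col_order=groups_present)
        if ordinal_flag:
            stat, df, p = mh_linear_association(tab)
            test = "mantel-haenszel"
        else:
            stat, df, p = chi2_independence(tab)
            test = "chi2"
        row = {"variable": var, "test": test, "statistic": stat, "p": p,
               "significant_pairs": ""}
        for j, g in enumerate(groups_present):
            col = tab.counts[:, j]
            row[g] = "; ".join(
                f"{lab}: {int(c)} ({100 * c / max(col.sum(), 1):.1f}%)"
                for lab, c in zip(tab.row_labels, col)
            )
        rows.append(row)
    return pd.DataFrame(rows)
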