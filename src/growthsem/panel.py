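"""Long-format longitudinal panel data: I/O, BMI, weight status, inclusion filtering.

A panel holds one row per subject x wave with three physical-activity (PA)
Likert items, three healthy-dietary-behavior (HDB) Likert items, measured
height/weight (hence BMI), and time-invariant baseline covariates.  Missing
values are represented as NaN (an explicit mask is derivable via
``pandas.isna``); they are never imputed here.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_RANGES",
    "PA_ITEMS",
    "HDB_ITEMS",
    "ANALYSIS_VARS",
    "PanelDataset",
    "compute_bmi",
    "classify_weight_status",
    "apply_inclusion_filter",
    "read_panel",
    "write_panel",
]

#: Inclusive (lo, hi) Likert ranges per item column.
ITEM_RANGES: dict[str, tuple[int, int]] = {
    "pa_aerobic": (0, 7),   # days/week of aerobic exercise, 8-point scale
    "pa_general": (1, 6),   # overall activity level, 6-point scale
    "pa_strength": (1, 4),  # strength exercise frequency, 4-point scale
    "hdb_fat": (1, 5),      # low-fat food habits, 5-point scale
    "hdb_grains": (1, 5),   # whole-grain habits, 5-point scale
    "hdb_protein": (1, 5),  # plant-protein habits, 5-point scale
}

PA_ITEMS = ["pa_aerobic", "pa_general", "pa_strength"]
HDB_ITEMS = ["hdb_fat", "hdb_grains", "hdb_protein"]

#: Variables that must all be present for a wave to count as "valid".
ANALYSIS_VARS = ["bmi"] + PA_ITEMS + HDB_ITEMS

COVARIATE_COLS = ["gender", "age", "race", "education", "income", "smoking", "alcohol"]

REQUIRED_COLS = (
    ["subject_id"]
    + COVARIATE_COLS
    + ["wave"]
    + PA_ITEMS
    + HDB_ITEMS
    + ["height_cm", "weight_kg"]
)

#: Columns the reader accepts beyond the required set.  ``bmi`` is recomputed
#: when absent; the two ``*_score`` columns are continuous process scores the
#: synthetic generator emits alongside the Likert items.
OPTIONAL_COLS = ["bmi", "pa_score", "hdb_score"]


def compute_bmi(height_cm, weight_kg):
    """Body mass index, kg/m^2, from height in cm and weight in kg.

    Vectorized; NaN inputs give NaN.  Nonpositive height or weight raises.
    """
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    if np.any(h[~np.isnan(h)] <= 0) or np.any(w[~np.isnan(w)] <= 0):
        raise ValueError("height_cm and weight_kg must be positive")
    out = w / (h / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def classify_weight_status(bmi):
    """Map BMI to 'normal' (<25), 'overweight' (25-29.9) or 'obese' (>=30).

    The overweight band is half-open: 25 <= bmi < 30.
    """
    b = np.asarray(bmi, dtype=float)
    if np.any(b[~np.isnan(b)] <= 0):
        raise ValueError("bmi must be positive")
    cats = np.where(b < 25, "normal", np.where(b < 30, "overweight", "obese"))
    cats = np.where(np.isnan(b), None, cats)
    return cats.item() if cats.ndim == 0 else cats


@dataclass
class PanelDataset:
    """A longitudinal panel in long format (one row per subject x wave).

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain ``REQUIRED_COLS``; ``bmi`` is recomputed from
        height/weight where absent or missing.
    wave_count : int
        Number of annual waves (default 7, indexed 0..6).
    """

    data: pd.DataFrame
    wave_count: int = 7
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self):
        if not self._validated:
            self.data = _validate_frame(self.data, self.wave_count)
            self._validated = True

    # -- basic accessors -------------------------------------------------
    @property
    def subjects(self) -> np.ndarray:
        """Subject ids in first-appearance order."""
        return self.data["subject_id"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def baseline(self) -> pd.DataFrame:
        """One row per subject: covariates plus wave-0 BMI and weight status."""
        first = self.data.sort_values("wave").groupby("subject_id", sort=False)
        base = first[COVARIATE_COLS].first().reset_index()
        w0 = self.data[self.data["wave"] == 0][["subject_id", "bmi"]]
        base = base.merge(w0.rename(columns={"bmi": "bmi0"}), on="subject_id", how="left")
        ws = np.array([None] * len(base), dtype=object)
        ok = base["bmi0"].notna().to_numpy()
        if ok.any():
            ws[ok] = classify_weight_status(base.loc[ok, "bmi0"].to_numpy())
        base["weight_status"] = ws
        # preserve original subject order
        order = pd.Index(self.subjects, name="subject_id")
        return base.set_index("subject_id").loc[order].reset_index()

    def valid_wave_counts(self) -> pd.Series:
        """Number of waves per subject at which all analysis variables are present."""
        present = self.data[ANALYSIS_VARS].notna().all(axis=1)
        counts = present.groupby(self.data["subject_id"], sort=False).sum()
        return counts.reindex(self.subjects, fill_value=0).astype(int)

    def to_wide(self, var: str, prefix: str | None = None) -> pd.DataFrame:
        """Pivot one repeated measure to subjects x waves (columns var0..var6)."""
        prefix = var if prefix is None else prefix
        wide = self.data.pivot_table(
            index="subject_id", columns="wave", values=var, aggfunc="first", dropna=False
        )
        wide = wide.reindex(columns=range(self.wave_count))
        wide.columns = [f"{prefix}{t}" for t in range(self.wave_count)]
        return wide.loc[pd.Index(self.subjects)]

    def __len__(self) -> int:
        return len(self.data)


def _validate_frame(df: pd.DataFrame, wave_count: int) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"panel is missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in REQUIRED_COLS + OPTIONAL_COLS]
    if unknown:
        raise ValueError(f"unknown panel columns: {unknown}")
    df = df.copy()

    dup = df.duplicated(subset=["subject_id", "wave"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"duplicate subject x wave at row {row}")
    waves = df["wave"].to_numpy()
    if np.any((waves < 0) | (waves >= wave_count) | (waves != waves.astype(int))):
        raise ValueError(f"wave indices must be integers in 0..{wave_count - 1}")
    for col, (lo, hi) in ITEM_RANGES.items():
        v = df[col].to_numpy(dtype=float)
        bad = ~np.isnan(v) & ((v < lo) | (v > hi) | (v != np.round(v)))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{col} value {v[bad][0]!r} out of Likert range [{lo},{hi}] at row {row}"
            )
    for col in ("education", "income"):
        v = df[col].to_numpy(dtype=float)
        bad = ~np.isnan(v) & ~np.isin(v, [1, 2, 3, 4])
        if bad.any():
            raise ValueError(f"{col} must be in {{1,2,3,4}}")
    alc = df["alcohol"].to_numpy(dtype=float)
    if np.any(alc[~np.isnan(alc)] < 0):
        raise ValueError("alcohol must be nonnegative")

    # BMI: recompute where absent, cross-check where present
    hw_bmi = np.full(len(df), np.nan)
    h = df["height_cm"].to_numpy(dtype=float)
    w = df["weight_kg"].to_numpy(dtype=float)
    ok = ~np.isnan(h) & ~np.isnan(w)
    if ok.any():
        hw_bmi[ok] = compute_bmi(h[ok], w[ok])
    if "bmi" not in df.columns:
        df["bmi"] = hw_bmi
    else:
        b = df["bmi"].to_numpy(dtype=float)
        fill = np.isnan(b) & ~np.isnan(hw_bmi)
        b = np.where(fill, hw_bmi, b)
        both = ~np.isnan(b) & ~np.isnan(hw_bmi)
        if np.any(np.abs(b[both] - hw_bmi[both]) > 1e-6):
            raise ValueError("stored bmi disagrees with weight/(height/100)^2")
        df["bmi"] = b
    return df


def apply_inclusion_filter(panel: PanelDataset, min_valid_waves: int = 5) -> PanelDataset:
    """Keep subjects with at least ``min_valid_waves`` waves at which BMI and
    all six behavior items are present.  Subject order is preserved.
    """
    if not 1 <= min_valid_waves <= panel.wave_count:
        raise ValueError("min_valid_waves must be in 1..wave_count")
    counts = panel.valid_wave_counts()
    keep = set(counts[counts >= min_valid_waves].index)
    out = panel.data[panel.data["subject_id"].isin(keep)].reset_index(drop=True)
    return PanelDataset(out, wave_count=panel.wave_count, _validated=True)


_NA = ""


def write_panel(panel: PanelDataset, path: str | os.PathLike) -> None:
    """Write a panel as delimited text (separator from extension: .tsv => tab)."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    panel.data.to_csv(path, sep=sep, index=False, na_rep=_NA)


def read_panel(path: str | os.PathLike | io.IOBase, wave_count: int = 7) -> PanelDataset:
    """Read a delimited-text panel (CSV, or TSV by extension).

    Empty fields and the sentinel ``NA`` are treated as missing.  Unknown
    columns, out-of-range Likert values and duplicated subject x wave rows
    raise ``ValueError`` naming the offender.
    """
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=True)
    if len(df) == 0:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in REQUIRED_COLS})
        df["subject_id"] = df["subject_id"].astype(object)
    return PanelDataset(df, wave_count=wave_count)
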