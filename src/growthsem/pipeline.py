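"""End-to-end study orchestration at desk scale.

``run_study`` drives the full analysis on a loaded or simulated panel:
inclusion filtering, per-wave PCA composites, stratified single-process
growth models for BMI/PA/HDB, the parallel model, and report tables
(descriptives, fit indices, growth parameters, association paths).
``recovery_experiment`` is the validation harness: it simulates cohorts
from a known parameter set, refits the parallel model and summarizes bias,
empirical SE and confidence-interval coverage per structural path.
"""

from __future__ import annotations

import datetime
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fitstats, study
from .composites import PCSScorer
from .descriptives import baseline_table
from .growth import GrowthCurveModel
from .panel import PanelDataset, apply_inclusion_filter, read_panel
from .parallel import ParallelGrowthCurveModel, extract_associations
from .simulate import SimulationConfig, default_config, simulate_parallel_cohort

__all__ = ["StudyConfig", "run_study", "recovery_experiment", "wide_from_panel"]

DEFAULT_COVARIATES = ("age", "race", "education", "income", "smoking", "alcohol")


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    input_path: str | None = None            # panel file; None => simulate
    simulation: SimulationConfig | None = None
    out_dir: str = "study_out"
    estimator: str = "fiml"                  # 'ml' or 'fiml'
    growth: str = "linear"                   # 'linear', 'quadratic' or 'compare'
    inclusion_threshold: int = 5
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    seed: int = 0
    rmsea_n: str = "n-1"
    pcs_scope: str = "per_wave"
    min_stratum_n: int = 100                 # below this the parallel model is skipped
    wave_residual_policy: str = "free"

    def __post_init__(self):
        if self.estimator not in ("ml", "fiml"):
            raise ValueError("estimator must be 'ml' or 'fiml'")
        if self.growth not in ("linear", "quadratic", "compare"):
            raise ValueError("growth must be 'linear', 'quadratic' or 'compare'")

    @classmethod
    def from_file(cls, path: str) -> "StudyConfig":
        """Load a study configuration from YAML or JSON.

        Recognized keys mirror the dataclass fields; a ``simulation``
        section may give ``n_per_stratum``, ``seed``, ``dropout_rate``,
        ``intermittent_rate`` and ``missingness`` (bool).
        """
        import json

        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) if not path.endswith(".json") else json.load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        sim_cfg = raw.pop("simulation", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        cfg = cls(**raw)
        if sim_cfg is not None:
            from .simulate import MissingnessSpec

            miss = None
            if not sim_cfg.get("missingness", True):
                miss = MissingnessSpec(0.0, 0.0)
            elif "dropout_rate" in sim_cfg or "intermittent_rate" in sim_cfg:
                miss = MissingnessSpec(
                    sim_cfg.get("dropout_rate", 0.04),
                    sim_cfg.get("intermittent_rate", 0.05),
                )
            cfg.simulation = default_config(
                n_per_stratum=sim_cfg.get("n_per_stratum"),
                seed=sim_cfg.get("seed", cfg.seed),
                missingness=miss,
            )
        return cfg


def encode_covariates(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariate design: binary dummies for race ('other'=1) and
    smoking ('yes'=1), ordinals and continuous variables as-is."""
    out = pd.DataFrame(index=df.index)
    for c in covariates:
        if c == "race":
            out[c] = (df[c].astype(str) == "other").astype(float)
        elif c == "smoking":
            out[c] = (df[c].astype(str) == "yes").astype(float)
        else:
            out[c] = df[c].astype(float)
    return out


def wide_from_panel(panel: PanelDataset, mapping: dict[str, str],
                    covariates=(), scored: pd.DataFrame | None = None) -> pd.DataFrame:
    """Subjects x waves frame with columns ``<prefix><t>`` per mapped
    variable plus encoded covariates.

    ``mapping`` maps output prefix -> long-format column (e.g.
    ``{'bmi': 'bmi', 'pa': 'pcs_pa'}``).  ``scored`` overrides the panel's
    long frame (used after composite scoring).
    """
    data = panel.data if scored is None else scored
    tmp = PanelDataset(data, wave_count=panel.wave_count, _validated=True)
    pieces = []
    for prefix, col in mapping.items():
        pieces.append(tmp.to_wide(col, prefix=prefix))
    wide = pd.concat(pieces, axis=1)
    if covariates:
        base = tmp.baseline().set_index("subject_id")
        enc = encode_covariates(base, covariates)
        wide = wide.join(enc)
    return wide


class _Log:
    def __init__(self):
        self.lines: list[str] = []

    def __call__(self, msg: str) -> None:
        ts = datetime.datetime.now().isoformat(timespec="seconds")
        self.lines.append(f"{ts} {msg}")

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.lines) + "\n")


def _fit_indices_row(indices: fitstats.FitIndices, **meta) -> dict:
    row = dict(meta)
    row.update(indices.row())
    return row


def run_study(config: StudyConfig) -> dict:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    Returns a dict with the four report tables, the log lines, and the
    fitted models per stratum.
    """
    log = _Log()
    rng_seed = config.seed
    if config.input_path is not None:
        panel = read_panel(config.input_path)
        log(f"loaded panel from {config.input_path}: {panel.n_subjects} subjects")
    else:
        sim = config.simulation or default_config(seed=rng_seed)
        panel = simulate_parallel_cohort(sim)
        log(f"simulated cohort (seed={sim.seed}): {panel.n_subjects} subjects")

    panel = apply_inclusion_filter(panel, config.inclusion_threshold)
    log(f"inclusion filter >= {config.inclusion_threshold} valid waves: "
        f"{panel.n_subjects} subjects retained")
    if panel.n_subjects == 0:
        raise RuntimeError("no subjects pass the inclusion filter")

    scorer = PCSScorer(scope=config.pcs_scope, wave_count=panel.wave_count)
    scored = scorer.fit(panel.data).transform(panel.data)
    log("PCA composites scored; per-wave PC1 shares: "
        + ", ".join(f"{r.battery}/w{int(r.wave)}={r.pc1_share:.3f}"
                    for r in scorer.report_.itertuples()))

    base = panel.baseline()
    # descriptives per gender (Table-1 layout)
    t1_frames = []
    for gender in ("male", "female"):
        sub = base[base["gender"] == gender]
        if len(sub) == 0:
            continue
        tab = baseline_table(sub)
        tab.insert(0, "gender", gender)
        t1_frames.append(tab)
    table1 = pd.concat(t1_frames, ignore_index=True) if t1_frames else pd.DataFrame()

    table2_rows, table3_rows, table4_rows = [], [], []
    fits = {}
    strata = [(g, s) for g in study.GENDERS for s in study.WEIGHT_STATUSES]
    for gender, status in strata:
        ids = set(base.loc[(base["gender"] == gender)
                           & (base["weight_status"] == status), "subject_id"])
        n_s = len(ids)
        if n_s == 0:
            log(f"stratum {gender}/{status}: empty, skipped")
            continue
        sub_panel = PanelDataset(
            panel.data[panel.data["subject_id"].isin(ids)].reset_index(drop=True),
            wave_count=panel.wave_count, _validated=True)
        sub_scored = scored[scored["subject_id"].isin(ids)]
        outcome_map = {"bmi": "bmi", "pa": "pcs_pa", "hdb": "pcs_hdb"}
        wide = wide_from_panel(sub_panel, outcome_map, config.covariates, scored=sub_scored)
        stratum_fits = {}
        for prefix in outcome_map:
            quad_flags = {"linear": [False], "quadratic": [True],
                          "compare": [False, True]}[config.growth]
            fitted = {}
            for quad in quad_flags:
                gm = GrowthCurveModel(
                    quadratic=quad, covariates=config.covariates,
                    estimator=config.estimator, outcome=prefix,
                    rmsea_n=config.rmsea_n,
                ).fit(wide)
                fitted[quad] = gm
                log(f"stratum {gender}/{status} outcome {prefix} "
                    f"{'quadratic' if quad else 'linear'}: n={gm.result_.n_effective} "
                    f"loglik={gm.loglik_:.2f} grad={gm.result_.grad_norm:.2e} "
                    f"converged={gm.converged_}")
            gm = fitted[quad_flags[-1] if config.growth == "quadratic" else quad_flags[0]]
            row = _fit_indices_row(
                gm.indices_, gender=gender, weight_status=status,
                model=f"lgcm_{prefix}", n=gm.result_.n_effective,
                converged=gm.converged_)
            if config.growth == "compare" and len(fitted) == 2:
                comp = fitstats.compare_linear_quadratic(
                    fitted[False].result_, fitted[True].result_)
                row.update({"lr_chi2": comp.lr_chi2, "lr_df": comp.lr_df,
                            "lr_p": comp.lr_p, "preferred": comp.preferred})
            table2_rows.append(row)
            stratum_fits[prefix] = gm
            for fname in gm.spec_.factor_names:
                est = gm.params_.get(f"nu_{fname}", np.nan)
                se = gm.se_.get(f"nu_{fname}", np.nan) if gm.se_ is not None else np.nan
                table3_rows.append({
                    "gender": gender, "weight_status": status, "outcome": prefix,
                    "parameter": fname, "estimate": est, "se": se})
            cov_is = gm.params_.get("psi_intercept_slope", np.nan)
            table3_rows.append({
                "gender": gender, "weight_status": status, "outcome": prefix,
                "parameter": "cov_intercept_slope", "estimate": cov_is,
                "se": gm.se_.get("psi_intercept_slope", np.nan)
                if gm.se_ is not None else np.nan})

        if n_s < config.min_stratum_n:
            log(f"stratum {gender}/{status}: n={n_s} < {config.min_stratum_n}, "
                "parallel model skipped")
        else:
            pm = ParallelGrowthCurveModel(
                covariates=config.covariates, estimator=config.estimator,
                wave_residual_policy=config.wave_residual_policy,
                rmsea_n=config.rmsea_n,
            ).fit(wide)
            log(f"stratum {gender}/{status} parallel: n={pm.result_.n_effective} "
                f"loglik={pm.loglik_:.2f} grad={pm.result_.grad_norm:.2e} "
                f"converged={pm.converged_}")
            table2_rows.append(_fit_indices_row(
                pm.indices_, gender=gender, weight_status=status,
                model="parallel", n=pm.result_.n_effective, converged=pm.converged_))
            ap = pm.associations_.to_frame()
            ap.insert(0, "weight_status", status)
            ap.insert(0, "gender", gender)
            table4_rows.append(ap)
            stratum_fits["parallel"] = pm
        fits[(gender, status)] = stratum_fits

    if not fits:
        raise RuntimeError("no stratum could be fitted")

    table2 = pd.DataFrame(table2_rows)
    table3 = pd.DataFrame(table3_rows)
    table4 = pd.concat(table4_rows, ignore_index=True) if table4_rows else pd.DataFrame()

    os.makedirs(config.out_dir, exist_ok=True)
    table1.to_csv(os.path.join(config.out_dir, "table1.csv"), index=False)
    table2.to_csv(os.path.join(config.out_dir, "table2.csv"), index=False)
    table3.to_csv(os.path.join(config.out_dir, "table3.csv"), index=False)
    table4.to_csv(os.path.join(config.out_dir, "table4.csv"), index=False)
    log(f"seed={config.seed}; tables written to {config.out_dir}")
    log.write(os.path.join(config.out_dir, "run.log"))

    return {"table1": table1, "table2": table2, "table3": table3,
            "table4": table4, "fits": fits, "log": log.lines}


_PATHS = ("a_pa", "a_hdb", "b_pa", "b_hdb", "c_pa", "c_hdb")


def recovery_experiment(
    params,
    covariate_marginals,
    gender: str,
    n: int,
    seed: int,
    reps: int = 1,
    estimator: str = "ml",
    compute_se: bool = True,
    use_likert_pipeline: bool = False,
) -> pd.DataFrame:
    """Simulate ``reps`` cohorts from ``params`` and refit the parallel model.

    By default the fit uses the generator's continuous behavior scores (the
    scale on which the generating paths are defined).  With
    ``use_likert_pipeline`` the discretized items are PCA-scored first,
    which attenuates the paths and is reported as-is.  Returns one row per
    structural path with mean estimate, bias, empirical SD and 95% CI
    coverage; raises if more than 20% of replicates fail to converge.
    """
    from .simulate import LikertSpec, StratumConfig, simulate_stratum

    truth = {
        "a_pa": params.paths_a[0], "a_hdb": params.paths_a[1],
        "b_pa": params.paths_b[0], "b_hdb": params.paths_b[1],
        "c_pa": params.paths_c[0], "c_hdb": params.paths_c[1],
    }
    rng = np.random.default_rng(seed)
    est_rows, cover_rows = [], []
    n_fail = 0
    for rep in range(reps):
        scfg = StratumConfig(gender=gender, weight_status="sim", n=n,
                             params=params, covariates=covariate_marginals)
        df = simulate_stratum(scfg, LikertSpec(), rng, id_prefix=f"r{rep}-")
        panel = PanelDataset(df, _validated=True)
        if use_likert_pipeline:
            scorer = PCSScorer()
            scored = scorer.fit(df).transform(df)
            mapping = {"bmi": "bmi", "pa": "pcs_pa", "hdb": "pcs_hdb"}
            wide = wide_from_panel(panel, mapping, scored=scored)
        else:
            wide = wide_from_panel(panel, {"bmi": "bmi", "pa": "pa_score",
                                           "hdb": "hdb_score"})
        pm = ParallelGrowthCurveModel(
            estimator=estimator, wave_residual_policy="none",
            compute_se=compute_se,
        ).fit(wide)
        if not pm.converged_:
            n_fail += 1
            continue
        est_rows.append({p: pm.params_[p] for p in _PATHS})
        if compute_se and pm.se_ is not None:
            cov = {}
            for p in _PATHS:
                lo = pm.params_[p] - 1.959963984540054 * pm.se_[p]
                hi = pm.params_[p] + 1.959963984540054 * pm.se_[p]
                cov[p] = lo <= truth[p] <= hi
            cover_rows.append(cov)
    if n_fail > 0.2 * reps:
        raise RuntimeError(f"{n_fail}/{reps} replicates failed to converge")
    est = pd.DataFrame(est_rows)
    out = []
    for p in _PATHS:
        row = {
            "path": p,
            "truth": truth[p],
            "mean_estimate": est[p].mean(),
            "bias": est[p].mean() - truth[p],
            "empirical_sd": est[p].std(ddof=1) if len(est) > 1 else np.nan,
            "n_converged": len(est),
            "n_failed": n_fail,
        }
        if cover_rows:
            row["coverage95"] = float(np.mean([c[p] for c in cover_rows]))
        out.append(row)
    return pd.DataFrame(out)
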