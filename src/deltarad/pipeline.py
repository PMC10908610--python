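"""End-to-end pipeline: simulate -> preprocess -> extract -> delta -> select ->
train -> evaluate, with provenance logging and a frozen-model validation step.

The discovery/validation separation is enforced by ordering: survival models
are retrained on the full discovery cohort, a ``freeze`` event is logged, and
every event after it is evaluation-only (asserted in an integration test).
Margin prediction follows the ensemble protocol instead: the cross-validation
models trained on discovery folds are kept and their output probabilities are
averaged on external subjects without refitting.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .delta import concat_bl_drf, delta_subtract
from .evalio import RunConfig, auc, write_feature_table
from .features import extract_all
from .mcom import ImiaConfig, imia_optimize
from .preprocess import preprocess_scan
from .selection import (CvPlan, cv_univariate_screen, drop_below_half,
                        forward_cox_select, spearman_prune)
from .survival import fuse_scores, label_at_horizon, logrank, median_stratify
from .synthdata import (CohortSpec, PhantomSpec, StentSpec, cohort_to_frame,
                        make_phantom_pair, simulate_cohort)

__all__ = ["PipelineResult", "run_pipeline", "simulate_imaging_cohort",
           "clinical_design_matrix"]

#: Standardized log-hazard coefficients driving simulated survival outcomes.
_DEFAULT_SURVIVAL_BETAS = {
    "drf.glcm.contrast.L32": 0.8,
    "pre.intensity.mean": 0.5,
}
#: Standardized log-odds coefficients driving simulated R1 margin status.
_DEFAULT_MARGIN_BETAS = {
    "drf.glcm.contrast.L32": 1.0,
    "pre.geometry.volume": 0.6,
}


@dataclass
class PipelineResult:
    config: RunConfig
    bldrf: pd.DataFrame
    clinical: pd.DataFrame
    report: dict
    provenance: list = field(default_factory=list)

    def log(self, stage: str, **detail) -> None:
        self.provenance.append({"stage": stage, "t": _time.time(), **detail})


def simulate_imaging_cohort(n_subjects: int, seed: int,
                            grid_shape=(48, 48, 32),
                            spacing=(1.0, 1.0, 2.0)):
    """Per-subject phantom pairs with varied size, shrinkage and texture;
    every fourth subject carries a biliary stent."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_subjects):
        radii = tuple(rng.uniform(8.0, 12.0, size=3))
        stent = None
        if i % 4 == 3:
            centre = tuple((n - 1) * s / 2.0 for n, s in zip(grid_shape, spacing))
            stent = StentSpec(center=(centre[0] + radii[0] * 0.5, centre[1],
                                      centre[2]),
                              radius=2.0, axis=2, hu=3000.0)
        specs.append(PhantomSpec(
            grid_shape=grid_shape, spacing=spacing, tumor_radii=radii,
            shrinkage=float(rng.uniform(0.5, 1.0)),
            texture_mu=float(rng.uniform(50, 70)),
            texture_sigma=float(rng.uniform(20, 40)),
            texture_corr_len=float(rng.uniform(2.0, 5.0)),
            stent=stent, seed=int(rng.integers(2 ** 31 - 1))))
    return specs


def _extract_subject(spec: PhantomSpec, cfg: RunConfig) -> tuple[pd.Series, pd.Series]:
    (vol_pre, m_pre), (vol_post, m_post) = make_phantom_pair(spec)
    out = []
    for vol, m in ((vol_pre, m_pre), (vol_post, m_post)):
        v, mm = preprocess_scan(vol, m, *cfg.hu_window, cfg.target_spacing)
        out.append(extract_all(v, mm, cfg.quantization_levels))
    return out[0], out[1]


def clinical_design_matrix(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric preoperative clinical covariates: log CA19-9 before treatment,
    the >=50%-decrease flag, and ordinal resectability."""
    resec_code = {"resectable": 0, "borderline": 1, "locally_advanced": 2,
                  "metastatic": 3}
    return pd.DataFrame({
        "log_ca199_pre": np.log1p(clinical["ca199_pre"]),
        "ca199_delta_flag": clinical["ca199_delta_flag"].astype(float),
        "resectability": clinical["resectability"].map(resec_code).astype(float),
    }, index=clinical.index)


def _clean_features(df: pd.DataFrame, max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Drop features missing in more than 20% of subjects; median-impute the
    rest; drop constant columns (carry no ranking information)."""
    keep = df.columns[df.isna().mean() <= max_missing_frac]
    out = df[keep].copy()
    out = out.fillna(out.median())
    nunique = out.nunique()
    return out.loc[:, nunique > 1]


def _survival_branch(result: PipelineResult, bldrf, clin_X, clinical, task, cfg,
                     plan) -> dict:
    time_col = clinical[f"{task}_time"].to_numpy(float)
    event_col = clinical[f"{task}_event"].to_numpy(int)
    y = (time_col, event_col)

    sr = cv_univariate_screen(bldrf, y, plan, task)
    sr = spearman_prune(bldrf, drop_below_half(sr), cfg.spearman_threshold)
    result.log("screen", task=task, kept=len(sr.kept))
    sel, model = forward_cox_select(bldrf[sr.kept], time_col, event_col, plan,
                                    max_k=cfg.max_features, rank_order=sr.kept)
    result.log("fit", task=task, model="bldrf", features=sel)

    sr_c = cv_univariate_screen(clin_X, y, plan, task)
    sr_c = spearman_prune(clin_X, drop_below_half(sr_c), cfg.spearman_threshold)
    sel_c, model_c = forward_cox_select(clin_X[sr_c.kept], time_col, event_col,
                                        plan, max_k=cfg.max_features,
                                        rank_order=sr_c.kept)
    result.log("fit", task=task, model="clinical", features=sel_c)

    scores_r = model.predict_scores(bldrf)
    scores_c = model_c.predict_scores(clin_X)
    fused = fuse_scores(scores_r, scores_c,
                        (model.score_mean, model.score_sd),
                        (model_c.score_mean, model_c.score_sd))
    strat = median_stratify(fused, float(np.median(fused)))
    hi = strat.group == "high"
    try:
        lr_stat, lr_p = logrank(time_col[hi], event_col[hi],
                                time_col[~hi], event_col[~hi])
    except ValueError:
        lr_stat, lr_p = float("nan"), float("nan")

    horizon_auc = {}
    for h in cfg.horizons_months:
        lab = label_at_horizon(time_col, event_col, h)
        use = lab != "excluded"
        ybin = (lab[use] == "event").astype(int)
        if len(np.unique(ybin)) == 2:
            horizon_auc[int(h)] = auc(ybin, fused[use])
    return {
        "selected_bldrf": sel, "selected_clinical": sel_c,
        "models": {"bldrf": model, "clinical": model_c},
        "fused_scores": fused, "logrank_p": lr_p,
        "horizon_auc": horizon_auc,
    }


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute the full synthetic study and return tables, models and report."""
    cfg = config
    result = PipelineResult(cfg, bldrf=None, clinical=None, report={})
    result.log("start", version=__version__, seed=cfg.seed,
               config_hash=cfg.config_hash())

    # --- discovery cohort: images -> features -------------------------------
    grid3 = tuple(cfg.grid_shape)
    specs = simulate_imaging_cohort(cfg.n_subjects, cfg.seed,
                                    grid_shape=(grid3[0], grid3[1],
                                                max(grid3[2] // 2, 16)))
    pre_rows, post_rows = [], []
    for i, spec in enumerate(specs):
        pre, post = _extract_subject(spec, cfg)
        pre_rows.append(pre.rename(f"s{i:03d}"))
        post_rows.append(post.rename(f"s{i:03d}"))
    pre_df = pd.DataFrame(pre_rows)
    post_df = pd.DataFrame(post_rows)
    result.log("extract", n_subjects=cfg.n_subjects, n_features=pre_df.shape[1])

    drf_rows = [delta_subtract(pre_df.loc[s], post_df.loc[s]) for s in pre_df.index]
    bldrf = pd.DataFrame(
        [concat_bl_drf(pre_df.loc[s], d) for s, d in zip(pre_df.index, drf_rows)])
    result.log("delta", n_bldrf=bldrf.shape[1])

    # --- outcomes -----------------------------------------------------------
    cspec = CohortSpec(n_subjects=cfg.n_subjects,
                       feature_betas=_DEFAULT_SURVIVAL_BETAS,
                       margin_betas=_DEFAULT_MARGIN_BETAS,
                       standardize=True, seed=cfg.seed + 1)
    clinical = cohort_to_frame(simulate_cohort(cspec, bldrf))
    clin_X = clinical_design_matrix(clinical)
    result.log("simulate_outcomes", n=len(clinical))

    result.bldrf = bldrf
    result.clinical = clinical
    plan = CvPlan(cfg.cv_repeats, cfg.cv_folds, cfg.seed)
    bldrf_clean = _clean_features(bldrf)

    report: dict = {"n_subjects": cfg.n_subjects,
                    "n_features_per_scan": pre_df.shape[1],
                    "n_bldrf_features": bldrf.shape[1]}
    for task in ("os", "dfs"):
        branch = _survival_branch(result, bldrf_clean, clin_X, clinical, task,
                                  cfg, plan)
        report[task] = {
            "selected_bldrf": branch["selected_bldrf"],
            "selected_clinical": branch["selected_clinical"],
            "logrank_p": branch["logrank_p"],
            "horizon_auc": branch["horizon_auc"],
        }
        report.setdefault("_models", {})[task] = branch["models"]

    # --- margin (mCOM, discovery CV) ---------------------------------------
    margin_labels = (clinical["margin"] == "R0").astype(int).to_numpy()
    mcom_report = {}
    if len(np.unique(margin_labels)) == 2:
        sr_m = cv_univariate_screen(bldrf_clean, margin_labels, plan, "margin")
        sr_m = spearman_prune(bldrf_clean, drop_below_half(sr_m),
                              cfg.spearman_threshold)
        top = sr_m.kept[:20]
        tables = {"clinical": clin_X, "radiomic": bldrf_clean[top]}
        mplan = CvPlan(1, min(cfg.cv_folds, 3), cfg.seed)
        mres = imia_optimize(tables, margin_labels, mplan,
                             ImiaConfig(population=cfg.mcom_population,
                                        generations=cfg.mcom_generations))
        result.log("fit", task="margin", model="mcom",
                   objectives=list(mres.best.objectives))
        mcom_report = {"objectives": list(mres.best.objectives),
                       "youden_j": mres.best.youden_j,
                       "cv_auc": mres.best.cv_auc,
                       "archive_size": len(mres.archive.members)}
        report["_mcom"] = mres
    report["margin"] = mcom_report

    # --- freeze, then external validation ----------------------------------
    result.log("freeze")
    if cfg.n_validation > 0:
        val_specs = simulate_imaging_cohort(
            cfg.n_validation, cfg.seed + 1000,
            grid_shape=(grid3[0], grid3[1], max(grid3[2] // 2, 16)))
        vp, vq = [], []
        for i, spec in enumerate(val_specs):
            a, b = _extract_subject(spec, cfg)
            vp.append(a.rename(f"v{i:03d}"))
            vq.append(b.rename(f"v{i:03d}"))
        vpre, vpost = pd.DataFrame(vp), pd.DataFrame(vq)
        vbldrf = pd.DataFrame([
            concat_bl_drf(vpre.loc[s], delta_subtract(vpre.loc[s], vpost.loc[s]))
            for s in vpre.index])
        vclin = cohort_to_frame(simulate_cohort(
            CohortSpec(n_subjects=cfg.n_validation,
                       feature_betas=_DEFAULT_SURVIVAL_BETAS,
                       margin_betas=_DEFAULT_MARGIN_BETAS,
                       standardize=True, seed=cfg.seed + 1001), vbldrf))
        from .survival import concordance_index
        val_report = {}
        for task in ("os", "dfs"):
            model = report["_models"][task]["bldrf"]
            feats = [f for f in model.features if f in vbldrf.columns]
            if len(feats) == len(model.features):
                scores = model.predict_scores(vbldrf.fillna(vbldrf.median()))
                val_report[task] = {"c_index": concordance_index(
                    vclin[f"{task}_time"], vclin[f"{task}_event"], scores)}
        report["validation"] = val_report
        result.log("evaluate", cohort="validation", **{
            k: v.get("c_index") for k, v in val_report.items()})

    result.report = report
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_feature_table(pre_df, outdir / "features_pre.csv")
        write_feature_table(post_df, outdir / "features_post.csv")
        write_feature_table(bldrf, outdir / "bldrf.csv")
        clinical.to_csv(outdir / "clinical.csv", index_label="subject")
        serializable = {k: v for k, v in report.items() if not k.startswith("_")}
        (outdir / "report.json").write_text(json.dumps(serializable, indent=2))
        models = {task: {name: m.to_dict() for name, m in d.items()}
                  for task, d in report.get("_models", {}).items()}
        (outdir / "models.json").write_text(json.dumps(models, indent=2))
        (outdir / "provenance.json").write_text(
            json.dumps(result.provenance, indent=2))
        cfg.to_yaml(outdir / "config.yaml")
    return result
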