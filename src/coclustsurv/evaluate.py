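"""Evaluation: time-dependent AUC, summed C-index curves, and the
end-to-end comparison driver.

The comparison driver reproduces the full analysis protocol on one cohort:
feature selection, tri-factorization stratification at K_s = 2 and 3 with
log-rank testing, the K_f sweep of the three risk models against a PCA arm
and clinical-only models, and ROC/AUC for three nested feature tiers
(clinical; clinical + inflammatory markers; clinical + inflammatory +
meta-features) on a held-out validation split.

The ROC endpoint under right censoring is the cumulative/dynamic AUC at a
fixed horizon (default 36 months, near the cohort's mean overall survival)
with inverse-probability-of-censoring weights from the Kaplan-Meier
estimate of the censoring distribution.  A plain binary mode (event by
horizon, censored-before-horizon excluded) is provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sksurv.metrics import cumulative_dynamic_auc

from . import trifactor
from .baselines import build_clinical_design, pca_reduce
from .cohort import GeneratorConfig, SyntheticCohort, generate_cohort
from .containers import SurvivalData
from .models import (
    MODEL_KINDS,
    _stratified_folds,
    concordance,
    fit_model,
    repeated_kfold_cindex,
    split_train_validation,
    sweep_kf,
)
from .selection import select_features
from .stratify import km_median, logrank, pairwise_logrank

__all__ = [
    "ipcw_auc",
    "binary_auc_at_horizon",
    "mean_model_auc",
    "summed_cindex_curve",
    "EvaluationConfig",
    "EvaluationReport",
    "run_full_comparison",
    "write_report",
]


def ipcw_auc(
    risk: np.ndarray,
    surv: SurvivalData,
    horizon_months: float,
    surv_train: SurvivalData | None = None,
) -> float:
    """Cumulative/dynamic AUC at a horizon with IPC weighting.

    Cases are subjects with an event by the horizon, controls those still
    at risk after it; censoring weights come from the Kaplan-Meier censoring
    estimator fitted on ``surv_train`` (defaults to ``surv`` itself).
    """
    risk = np.asarray(risk, dtype=float)
    t = surv.time_months
    if not (surv.event[t <= horizon_months].sum() > 0):
        raise ValueError("no events before the horizon")
    if not (t > horizon_months).any():
        raise ValueError("no subjects at risk beyond the horizon")
    train = surv_train if surv_train is not None else surv

    def _clip(s: SurvivalData) -> np.ndarray:
        # administratively censor just past the horizon: the AUC at the
        # horizon is unchanged (cases/controls identical, censoring KM
        # identical on [0, horizon]) but the IPC weights never have to be
        # evaluated beyond the training sample's support
        cap = horizon_months * (1.0 + 1e-6)
        time = np.minimum(s.time_months, cap)
        event = np.where(s.time_months <= horizon_months, s.event, 0)
        return np.array(
            list(zip(event.astype(bool), time)), dtype=[("event", "?"), ("time", "<f8")]
        )

    auc, _ = cumulative_dynamic_auc(_clip(train), _clip(surv), risk, [horizon_months])
    return float(auc[0])


def binary_auc_at_horizon(
    risk: np.ndarray, surv: SurvivalData, horizon_months: float
) -> float:
    """Plain AUC for the label "event by horizon"; censored-before-horizon excluded."""
    from sklearn.metrics import roc_auc_score

    t, e = surv.time_months, surv.event
    keep = (e == 1) | (t > horizon_months)
    label = ((t <= horizon_months) & (e == 1))[keep]
    if label.all() or not label.any():
        raise ValueError("horizon leaves a single outcome class")
    return float(roc_auc_score(label, np.asarray(risk)[keep]))


def mean_model_auc(aucs: dict[str, float] | np.ndarray) -> tuple[float, float]:
    """Mean and sample sd of the per-model AUCs (cox, cox_lasso, rsf)."""
    if isinstance(aucs, dict):
        missing = [k for k in MODEL_KINDS if k not in aucs]
        if missing:
            raise ValueError(f"missing model AUCs: {missing}")
        vals = np.array([aucs[k] for k in MODEL_KINDS], dtype=float)
    else:
        vals = np.asarray(aucs, dtype=float)
    if len(vals) != 3 or not np.all(np.isfinite(vals)):
        raise ValueError("expected three finite AUC values")
    return float(vals.mean()), float(vals.std(ddof=1))


def summed_cindex_curve(cv_table: pd.DataFrame) -> pd.DataFrame:
    """Sum of mean C-indices over the three models per K_f, plus the argmax.

    Expects the tidy frame from :func:`coclustsurv.models.sweep_kf`.
    """
    means = cv_table.groupby(["kf", "model"])["cindex"].mean().unstack()
    missing = [m for m in MODEL_KINDS if m not in means.columns]
    if missing or means[list(MODEL_KINDS)].isna().any().any():
        raise ValueError(f"incomplete model grid: missing {missing or 'entries'}")
    out = means[list(MODEL_KINDS)].copy()
    out["summed"] = out.sum(axis=1)
    out.attrs["argmax_kf"] = int(out["summed"].idxmax())
    return out


@dataclass(frozen=True)
class EvaluationConfig:
    """End-to-end driver settings (desk-scale defaults)."""

    generator: GeneratorConfig = GeneratorConfig()
    icc_threshold: float = 0.75
    r_threshold_pet: float = 0.76
    r_threshold_ct: float = 0.40
    k_s: int = 3
    k_f: int = 9
    kf_grid: tuple[int, ...] = tuple(range(2, 11))
    cv_folds: int = 3
    sweep_reps: int = 2
    clinical_cv_reps: int = 10
    sweep_rsf_trees: int = 150
    train_fraction: float = 0.7
    auc_horizon_months: float = 36.0
    trifactor_restarts: int = 2
    trifactor_max_iter: int = 200
    seed: int = 0


@dataclass
class EvaluationReport:
    """All aggregated outputs of one full comparison run."""

    selection_summary: dict
    stratification: pd.DataFrame
    pairwise_p: dict[int, pd.DataFrame]
    sweep_two_way: pd.DataFrame
    sweep_pca: pd.DataFrame
    summed_two_way: pd.DataFrame
    summed_pca: pd.DataFrame
    clinical_cv: pd.DataFrame
    tier_auc: pd.DataFrame
    config: EvaluationConfig = None  # type: ignore[assignment]


def _sweep_pca(xv, surv, kf_grid, model_kinds, k, reps, seed, rsf_trees):
    """PCA analogue of the K_f sweep (fold-honest: PCA refit per fold)."""
    rows = []
    for dim in kf_grid:
        for rep in range(reps):
            rep_seed = int(np.random.default_rng([seed, dim, rep, 77]).integers(2**31 - 1))
            for f, (tr, va) in enumerate(_stratified_folds(surv.event, k, rep_seed)):
                scores_tr, (scaler, pca) = pca_reduce(xv[tr], dim, return_model=True)
                scores_va = pca.transform(scaler.transform(xv[va]))
                for kind in model_kinds:
                    kw = {"n_trees": rsf_trees} if kind == "rsf" else {}
                    model = fit_model(kind, scores_tr, surv.subset(tr), seed=rep_seed + f, **kw)
                    rows.append(
                        {
                            "kf": dim,
                            "model": kind,
                            "rep": rep,
                            "fold": f,
                            "cindex": concordance(model.predict(scores_va), surv.subset(va)),
                        }
                    )
    return pd.DataFrame(rows)


def _tier_auc_table(cohort: SyntheticCohort, meta_all, cfg: EvaluationConfig) -> pd.DataFrame:
    """Validation (and training) IPCW AUC for the three nested feature tiers."""
    surv = cohort.survival
    tr, va = split_train_validation(
        len(surv), cfg.train_fraction, stratify_on=surv.event, seed=cfg.seed
    )
    tier1 = build_clinical_design(cohort.clinical).to_numpy(float)
    tier2 = build_clinical_design(cohort.clinical, include_inflammatory=True).to_numpy(float)
    tier3 = np.hstack([tier2, meta_all])
    rows = []
    for tier_name, design in (
        ("clinical", tier1),
        ("clinical+inflammatory", tier2),
        ("clinical+inflammatory+radiomic", tier3),
    ):
        per_model = {}
        per_model_train = {}
        for kind in MODEL_KINDS:
            model = fit_model(kind, design[tr], surv.subset(tr), seed=cfg.seed)
            per_model[kind] = ipcw_auc(
                model.predict(design[va]),
                surv.subset(va),
                cfg.auc_horizon_months,
                surv_train=surv.subset(tr),
            )
            per_model_train[kind] = ipcw_auc(
                model.predict(design[tr]), surv.subset(tr), cfg.auc_horizon_months
            )
        mean_va, sd_va = mean_model_auc(per_model)
        mean_tr, sd_tr = mean_model_auc(per_model_train)
        rows.append(
            {
                "tier": tier_name,
                **{f"auc_val_{k}": v for k, v in per_model.items()},
                "auc_val_mean": mean_va,
                "auc_val_sd": sd_va,
                "auc_train_mean": mean_tr,
                "auc_train_sd": sd_tr,
            }
        )
    return pd.DataFrame(rows)


def run_full_comparison(
    config: EvaluationConfig,
    cohort: SyntheticCohort | None = None,
) -> EvaluationReport:
    """Execute the whole protocol on one (generated or supplied) cohort."""
    cfg = config
    if cohort is None:
        cohort = generate_cohort(cfg.generator)
    surv = cohort.survival

    # 1. reproducibility + redundancy selection
    report = select_features(
        cohort.features,
        cohort.features_rater2,
        icc_threshold=cfg.icc_threshold,
        threshold_pet=cfg.r_threshold_pet,
        threshold_ct=cfg.r_threshold_ct,
    )
    selected = cohort.features.select_features(report.final_features)
    selection_summary = {
        "n_input": cohort.features.n_features,
        "n_after_icc": len(report.kept_after_icc),
        "n_final": len(report.final_features),
    }

    x = trifactor.rescale_nonnegative(selected)
    tf_opts = {
        "n_restarts": cfg.trifactor_restarts,
        "max_iter": cfg.trifactor_max_iter,
    }

    # 2. stratification at K_s = 2 and 3 (independent refits)
    strat_rows, pairwise = [], {}
    for ks in (2, 3):
        fitted = trifactor.fit(x, ks, min(cfg.k_f, x.n_features), seed=cfg.seed, **tf_opts)
        labels = trifactor.assign_patient_clusters(fitted)
        lr = logrank(surv, labels)
        pairwise[ks] = pairwise_logrank(surv, labels)
        for g in np.unique(labels):
            idx = np.where(labels == g)[0]
            strat_rows.append(
                {
                    "k_s": ks,
                    "group": int(g),
                    "n": len(idx),
                    "events": int(surv.event[idx].sum()),
                    "median_months": km_median(surv.subset(idx)),
                    "overall_logrank_p": lr.p,
                }
            )
    stratification = pd.DataFrame(strat_rows)

    # 3. K_f sweep: two-way meta-features vs PCA, all three models
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sweep_two_way = sweep_kf(
            x,
            surv,
            k_s=cfg.k_s,
            kf_values=cfg.kf_grid,
            k=cfg.cv_folds,
            reps=cfg.sweep_reps,
            seed=cfg.seed,
            trifactor_opts=tf_opts,
            rsf_trees=cfg.sweep_rsf_trees,
        )
        sweep_pca = _sweep_pca(
            x.values,
            surv,
            cfg.kf_grid,
            MODEL_KINDS,
            cfg.cv_folds,
            cfg.sweep_reps,
            cfg.seed,
            cfg.sweep_rsf_trees,
        )
        summed_two_way = summed_cindex_curve(sweep_two_way)
        summed_pca = summed_cindex_curve(sweep_pca)

        # 4. clinical-only models under the same CV protocol
        clin_design = build_clinical_design(cohort.clinical, include_inflammatory=True)
        clin_rows = []
        for kind in MODEL_KINDS:
            cv = repeated_kfold_cindex(
                kind,
                clin_design,
                surv,
                k=cfg.cv_folds,
                reps=cfg.clinical_cv_reps,
                seed=cfg.seed,
            )
            clin_rows.append({"model": kind, "cindex_mean": cv.mean, "cindex_sd": cv.sd})
        clinical_cv = pd.DataFrame(clin_rows)

        # 5. feature-tier AUC analysis on the best K_f of the sweep
        best_kf = summed_two_way.attrs["argmax_kf"]
        fitted = trifactor.fit(x, cfg.k_s, best_kf, seed=cfg.seed, **tf_opts)
        meta_all = trifactor.meta_features(fitted).M
        tier_auc = _tier_auc_table(cohort, meta_all, cfg)

    return EvaluationReport(
        selection_summary=selection_summary,
        stratification=stratification,
        pairwise_p=pairwise,
        sweep_two_way=sweep_two_way,
        sweep_pca=sweep_pca,
        summed_two_way=summed_two_way,
        summed_pca=summed_pca,
        clinical_cv=clinical_cv,
        tier_auc=tier_auc,
        config=cfg,
    )


def write_report(report: EvaluationReport, out_dir: str | Path) -> list[Path]:
    """Serialize every table of the report plus a text summary; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = out / name
        df.to_csv(p, index=index)
        paths.append(p)

    _write(report.stratification, "stratification.csv")
    for ks, table in sorted(report.pairwise_p.items()):
        _write(table, f"pairwise_logrank_ks{ks}.csv", index=True)
    _write(report.sweep_two_way, "sweep_two_way.csv")
    _write(report.sweep_pca, "sweep_pca.csv")
    _write(report.summed_two_way, "summed_cindex_two_way.csv", index=True)
    _write(report.summed_pca, "summed_cindex_pca.csv", index=True)
    _write(report.clinical_cv, "clinical_cv.csv")
    _write(report.tier_auc, "tier_auc.csv")

    lines = [
        "full comparison summary",
        "=======================",
        f"features: {report.selection_summary['n_input']} -> "
        f"{report.selection_summary['n_after_icc']} (ICC) -> "
        f"{report.selection_summary['n_final']} (correlation pruning)",
        f"best K_f by summed C-index (two-way): {report.summed_two_way.attrs['argmax_kf']} "
        f"(summed = {report.summed_two_way['summed'].max():.3f})",
        f"best K_f by summed C-index (PCA): {int(report.summed_pca['summed'].idxmax())} "
        f"(summed = {report.summed_pca['summed'].max():.3f})",
        "tier mean validation AUC: "
        + ", ".join(
            f"{r.tier}={r.auc_val_mean:.3f}" for r in report.tier_auc.itertuples()
        ),
    ]
    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    paths.append(summary)
    return paths
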