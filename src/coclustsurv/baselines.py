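"""Comparison arms: K-means stratification, PCA meta-features, nested
parameter selection, and clinical-variable designs.

Both K-means and PCA standardize features internally (z-score): radiomic
features mix scales by orders of magnitude and both methods are scale
sensitive.  PCA component signs are fixed by making each loading vector's
largest-magnitude entry positive, so scores are reproducible across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from . import trifactor
from .containers import ClinicalTable, FeatureMatrix, SurvivalData
from .models import _stratified_folds, concordance, fit_model

__all__ = [
    "kmeans_cluster",
    "pca_reduce",
    "nested_param_select",
    "build_clinical_design",
    "CLINICAL_BASE",
    "INFLAMMATORY_MARKERS",
    "SUV_METRICS",
]

#: the base clinical tier: demographics + stage + nodal status
CLINICAL_BASE = ["age", "bmi", "t_stage_code", "lymph_node_positive"]
INFLAMMATORY_MARKERS = ["wbc", "nc", "lc", "plt", "nlr"]
SUV_METRICS = ["suv_max", "suv_mean", "suv_peak"]


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=float)


def kmeans_cluster(
    x, k: int, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """Lloyd's algorithm on z-scored features; best of ``n_init`` seeded starts."""
    if k < 1:
        raise ValueError("k must be at least 1")
    vals = _values(x)
    if k > vals.shape[0]:
        raise ValueError("k cannot exceed the number of patients")
    z = StandardScaler().fit_transform(vals)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(z)


def pca_reduce(
    x, n_components: int, return_model: bool = False
):
    """Scores on the top principal components of the standardized matrix."""
    vals = _values(x)
    n, f = vals.shape
    if not 1 <= n_components <= min(n, f):
        raise ValueError(f"n_components must lie in [1, {min(n, f)}]")
    scaler = StandardScaler()
    z = scaler.fit_transform(vals)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_components), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    pca.components_ *= flip[:, None]
    scores *= flip[None, :]
    if return_model:
        return scores, (scaler, pca)
    return scores


def _candidate_features(method, xv, tr, va, param, seed, trifactor_opts):
    """Training and held-out feature blocks for one grid value of one method."""
    if method == "two_way":
        fitted = trifactor.fit(xv[tr], k_s=trifactor_opts.get("k_s", 3), k_f=param,
                               seed=seed,
                               **{k: v for k, v in trifactor_opts.items() if k != "k_s"})
        m_tr = trifactor.meta_features(fitted).M
        _, m_va = trifactor.project_patients(xv[va], fitted.S, fitted.Y)
        return m_tr, m_va
    if method == "pca":
        scores, (scaler, pca) = pca_reduce(xv[tr], param, return_model=True)
        return scores, pca.transform(scaler.transform(xv[va]))
    raise ValueError(f"unknown method {method!r}")


def nested_param_select(
    x,
    surv: SurvivalData,
    method: str,
    param_grid: tuple[int, ...],
    outer_folds: int = 5,
    inner_folds: int = 3,
    model_kind: str = "cox",
    seed: int = 0,
    trifactor_opts: dict | None = None,
) -> dict:
    """Nested cross-validated dimension selection for ``two_way`` or ``pca``.

    Outer event-stratified folds score generalisation; within each outer
    training set an inner 3-fold CV picks the grid value with the highest
    mean held-out concordance, and the refit model is scored on the outer
    fold.  Returns the modal selected parameter and the outer C-index
    mean +- sd.
    """
    if not param_grid:
        raise ValueError("empty parameter grid")
    xv = _values(x)
    tf_opts = {"max_iter": 200, "tol": 1e-6, "n_restarts": 2}
    if trifactor_opts:
        tf_opts.update(trifactor_opts)
    outer = _stratified_folds(surv.event, outer_folds, seed)
    outer_scores, selected = [], []
    for o, (otr, ova) in enumerate(outer):
        if len(param_grid) == 1:
            best_param = param_grid[0]
        else:
            inner_mean = {}
            inner = _stratified_folds(surv.event[otr], inner_folds, seed + 1000 + o)
            for param in param_grid:
                vals = []
                for i, (itr, iva) in enumerate(inner):
                    tr, va = otr[itr], otr[iva]
                    m_tr, m_va = _candidate_features(
                        method, xv, tr, va, param, seed + o * 100 + i, tf_opts
                    )
                    model = fit_model(model_kind, m_tr, surv.subset(tr), seed=seed)
                    vals.append(concordance(model.predict(m_va), surv.subset(va)))
                inner_mean[param] = float(np.mean(vals))
            best_param = max(param_grid, key=lambda p: inner_mean[p])
        selected.append(best_param)
        m_tr, m_va = _candidate_features(
            method, xv, otr, ova, best_param, seed + 7 * o, tf_opts
        )
        model = fit_model(model_kind, m_tr, surv.subset(otr), seed=seed)
        outer_scores.append(concordance(model.predict(m_va), surv.subset(ova)))
    outer_scores = np.asarray(outer_scores)
    uniq, counts = np.unique(selected, return_counts=True)
    return {
        "best_param": int(uniq[np.argmax(counts)]),
        "selected_per_fold": selected,
        "outer_cindex_mean": float(outer_scores.mean()),
        "outer_cindex_sd": float(outer_scores.std(ddof=1)),
        "outer_cindex": outer_scores,
    }


def build_clinical_design(
    clin: ClinicalTable,
    include_inflammatory: bool = False,
    include_suv: bool = False,
) -> pd.DataFrame:
    """Numeric design matrix from the clinical table.

    The base tier is age, BMI, ordinal-coded T stage and nodal status;
    flags append the inflammatory markers (WBC, NC, LC, PLT, NLR) and the
    semi-quantitative SUV metrics.  Column order is fixed.
    """
    df = clin.data
    design = pd.DataFrame(
        {
            "age": df["age"].astype(float),
            "bmi": df["bmi"].astype(float),
            "t_stage_code": df["t_stage"].astype(float),
            "lymph_node_positive": df["lymph_node_positive"].astype(float),
        }
    )
    if include_inflammatory:
        for c in INFLAMMATORY_MARKERS:
            design[c] = df[c].astype(float)
    if include_suv:
        for c in SUV_METRICS:
            design[c] = df[c].astype(float)
    return design
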