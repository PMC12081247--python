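"""Mortality-risk models and the cross-validation / comparison protocol.

Three model families predict a real-valued mortality risk score from a
feature table (meta-features, PCA scores, or clinical covariates):

* ``cox`` — Cox proportional-hazards regression (Efron tie handling);
  risk score is the linear predictor.
* ``cox_lasso`` — L1-penalised Cox over a descending penalty path, the
  penalty chosen by inner k-fold cross-validation (held-out Breslow partial
  likelihood by default, concordance optionally), then refit on all data.
* ``rsf`` — random survival forest (log-rank splitting, 500 trees and a
  minimum of 5 samples per leaf by default); risk score is the ensemble
  cumulative-hazard summary.

Evaluation follows a repeated, event-stratified k-fold protocol (3 folds,
100 repetitions by default), scored by Harrell's concordance index, plus a
single stratified 7:3 train/validation split for held-out reporting.  The
K_f sweep refits the tri-factorization inside every training fold and
projects held-out patients by nonnegative least squares, so meta-features
never leak outcome-side information across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index as _lifelines_cindex
from sklearn.model_selection import StratifiedKFold
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis

from . import trifactor
from .containers import SurvivalData

__all__ = [
    "RiskModel",
    "CVSummary",
    "split_train_validation",
    "fit_cox",
    "fit_cox_lasso",
    "fit_rsf",
    "fit_model",
    "concordance",
    "repeated_kfold_cindex",
    "sweep_kf",
    "MODEL_KINDS",
]

MODEL_KINDS = ("cox", "cox_lasso", "rsf")


@dataclass
class RiskModel:
    """A fitted risk model: higher predicted score = higher mortality risk."""

    kind: str
    feature_names: list[str]
    predict_fn: Callable[[np.ndarray], np.ndarray]
    coef: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            x = x[self.feature_names].to_numpy(float)
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(self.feature_names):
            raise ValueError("feature count mismatch")
        return np.asarray(self.predict_fn(x), dtype=float).ravel()


@dataclass
class CVSummary:
    """Fold-level concordance indices from repeated k-fold CV."""

    fold_cindex: np.ndarray  # shape (reps, k)
    k: int
    reps: int
    seed: int

    @property
    def mean(self) -> float:
        return float(self.fold_cindex.mean())

    @property
    def sd(self) -> float:
        return float(self.fold_cindex.std(ddof=1))


def _as_2d(features: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(float), list(features.columns)
    arr = np.asarray(features, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def split_train_validation(
    n: int,
    train_fraction: float = 0.7,
    stratify_on: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-stratified random split with train size = round(n * fraction).

    Stratum allocations use largest-remainder rounding so the event
    proportion in the two parts differs by at most one subject's worth.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(n * train_fraction))
    if stratify_on is None:
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    strata = np.asarray(stratify_on)
    groups = np.unique(strata)
    if any((strata == g).sum() < 2 for g in groups):
        raise ValueError("every stratum needs at least 2 subjects")
    exact = {g: (strata == g).sum() * train_fraction for g in groups}
    alloc = {g: int(np.floor(v)) for g, v in exact.items()}
    short = n_train - sum(alloc.values())
    for g in sorted(groups, key=lambda g: exact[g] - alloc[g], reverse=True)[:short]:
        alloc[g] += 1
    train_idx: list[int] = []
    for g in groups:
        members = np.where(strata == g)[0]
        chosen = rng.permutation(len(members))[: alloc[g]]
        train_idx.extend(members[chosen])
    train = np.sort(np.asarray(train_idx))
    val = np.setdiff1d(np.arange(n), train)
    return train, val


def fit_cox(
    features: np.ndarray | pd.DataFrame,
    surv: SurvivalData,
    penalizer: float = 0.0,
) -> RiskModel:
    """Cox proportional hazards by partial-likelihood maximisation (Efron ties).

    If the unpenalised Newton iteration halts on a singular Hessian — which
    happens deterministically for rank-deficient designs such as
    meta-features, whose rank never exceeds the number of patient
    sub-clusters — the fit is retried with a small ridge penalty (1e-3) and
    the fallback is reported in the model metadata and as a warning.
    """
    x, names = _as_2d(features)
    if surv.n_events == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    if np.any(x.var(axis=0) == 0):
        bad = [names[j] for j in np.where(x.var(axis=0) == 0)[0]]
        raise ValueError(f"constant features: {bad}")
    df = pd.DataFrame(x, columns=names)
    df["time"] = surv.time_months
    df["event"] = surv.event
    ridge_fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph = CoxPHFitter(penalizer=penalizer)
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, np.linalg.LinAlgError):
            ridge_fallback = True
            cph = CoxPHFitter(penalizer=1e-3)
            cph.fit(df, duration_col="time", event_col="event")
    if ridge_fallback:
        warnings.warn(
            "Cox partial likelihood is flat (rank-deficient design); "
            "refit with ridge penalty 1e-3"
        )
    coef = cph.params_.to_numpy()
    if np.any(np.abs(coef) > 50):
        raise RuntimeError(
            "Cox fit produced unbounded coefficients (likely complete separation)"
        )
    return RiskModel(
        kind="cox",
        feature_names=names,
        predict_fn=lambda z: z @ coef,
        coef=coef,
        meta={"fitter": cph, "ridge_fallback": ridge_fallback},
    )


def _breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of linear predictors on held-out data."""
    order = np.argsort(-time, kind="stable")
    eta, time, event = eta[order], time[order], event[order]
    # running log-sum-exp over the risk set (subjects with time >= t)
    m = np.maximum.accumulate(eta)
    lse = np.log(np.cumsum(np.exp(eta - m[-1]))) + m[-1]
    ll = 0.0
    for i in np.where(event == 1)[0]:
        # risk set of subject i: everyone with time >= time_i; because ties
        # share the risk set, extend to the last index with the same time
        j = np.searchsorted(-time, -time[i], side="right") - 1
        ll += eta[i] - lse[j]
    return float(ll)


def fit_cox_lasso(
    features: np.ndarray | pd.DataFrame,
    surv: SurvivalData,
    inner_folds: int = 3,
    seed: int = 0,
    criterion: str = "loglik",
    penalty: float | None = None,
) -> RiskModel:
    """L1-penalised Cox with the penalty chosen by nested cross-validation.

    A descending penalty path is computed on the supplied data; each
    candidate is scored by inner event-stratified k-fold CV using the
    held-out Breslow partial likelihood (``criterion="loglik"``, default)
    or Harrell's C (``criterion="cindex"``).  The winning penalty is the
    sparsest one within one standard error of the best inner score (the
    glmnet ``lambda.1se`` convention); the model is then refit on all
    supplied data at that penalty.  Passing ``penalty`` skips the inner CV
    entirely.
    """
    x, names = _as_2d(features)
    y = surv.to_structured()
    if penalty is not None:
        net = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=[max(penalty, 1e-9)], tol=1e-9, max_iter=1_000_000
        )
        net.fit(x, y)
        coef = net.coef_[:, 0]
        return _lasso_model(names, coef, penalty)

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=30, alpha_min_ratio=0.01)
    path.fit(x, y)
    alphas = list(path.alphas_)

    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    scores = np.zeros((inner_folds, len(alphas)))
    for f, (tr, va) in enumerate(skf.split(x, surv.event)):
        net = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        net.fit(x[tr], y[tr])
        for a_idx, a in enumerate(alphas):
            eta = net.predict(x[va], alpha=a)
            if criterion == "loglik":
                scores[f, a_idx] = _breslow_loglik(
                    eta, surv.time_months[va], surv.event[va]
                )
            elif criterion == "cindex":
                scores[f, a_idx] = concordance(eta, surv.subset(va))
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
    # one-standard-error rule: the sparsest penalty whose inner-CV score is
    # within one SE of the best, the usual guard against the flat CV profile
    # of the partial likelihood
    mean_scores = scores.mean(axis=0)
    best_idx = int(np.argmax(mean_scores))
    se = scores[:, best_idx].std(ddof=1) / np.sqrt(inner_folds)
    eligible = np.where(mean_scores >= mean_scores[best_idx] - se)[0]
    chosen = int(eligible[np.argmax([alphas[i] for i in eligible])])
    best_alpha = alphas[chosen]
    coef = path.coef_[:, chosen]
    return _lasso_model(names, coef, best_alpha)


def _lasso_model(names: list[str], coef: np.ndarray, alpha: float) -> RiskModel:
    meta = {"alpha": float(alpha), "n_nonzero": int(np.count_nonzero(coef))}
    if meta["n_nonzero"] == 0:
        meta["constant_risk"] = True
        warnings.warn("all Lasso coefficients shrunk to zero; model is constant-risk")
    return RiskModel(
        kind="cox_lasso",
        feature_names=names,
        predict_fn=lambda z: z @ coef,
        coef=coef,
        meta=meta,
    )


def fit_rsf(
    features: np.ndarray | pd.DataFrame,
    surv: SurvivalData,
    n_trees: int = 500,
    min_leaf: int = 5,
    seed: int = 0,
) -> RiskModel:
    """Random survival forest (log-rank splits, seeded bootstrap)."""
    x, names = _as_2d(features)
    if len(surv) < 2 * min_leaf:
        raise ValueError("too few subjects for the requested minimum leaf size")
    forest = RandomSurvivalForest(
        n_estimators=n_trees,
        min_samples_leaf=min_leaf,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(x, surv.to_structured())
    return RiskModel(
        kind="rsf",
        feature_names=names,
        predict_fn=forest.predict,  # aggregated cumulative hazard
        meta={"n_trees": n_trees, "min_leaf": min_leaf, "forest": forest},
    )


def fit_model(
    kind: str,
    features: np.ndarray | pd.DataFrame,
    surv: SurvivalData,
    seed: int = 0,
    **kwargs,
) -> RiskModel:
    """Dispatch on model kind ("cox", "cox_lasso" or "rsf")."""
    if kind == "cox":
        return fit_cox(features, surv)
    if kind == "cox_lasso":
        return fit_cox_lasso(features, surv, seed=seed, **kwargs)
    if kind == "rsf":
        return fit_rsf(features, surv, seed=seed, **kwargs)
    raise ValueError(f"unknown model kind {kind!r}")


def concordance(risk: np.ndarray, surv: SurvivalData) -> float:
    """Harrell's concordance index of a risk score under right censoring.

    A pair is comparable when the shorter observed time carries an event
    (including time ties between an event and a censoring, where the event
    is treated as first); tied risk scores count 1/2.
    """
    risk = np.asarray(risk, dtype=float)
    if len(risk) != len(surv):
        raise ValueError("risk and survival lengths differ")
    # lifelines scores "higher prediction = longer survival"; negate risk
    try:
        return float(_lifelines_cindex(surv.time_months, -risk, surv.event))
    except ZeroDivisionError:
        raise ValueError("no comparable pairs") from None


def _stratified_folds(event: np.ndarray, k: int, seed: int):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(event)), event))


def repeated_kfold_cindex(
    model_kind: str,
    features: np.ndarray | pd.DataFrame,
    surv: SurvivalData,
    k: int = 3,
    reps: int = 100,
    seed: int = 0,
    **model_kwargs,
) -> CVSummary:
    """Repeated event-stratified k-fold CV scored by Harrell's C."""
    x, names = _as_2d(features)
    df = pd.DataFrame(x, columns=names)
    if len(surv) < 3 * k:
        raise ValueError("too few subjects for the requested fold count")
    out = np.zeros((reps, k))
    for rep in range(reps):
        rep_seed = int(np.random.default_rng([seed, rep]).integers(2**31 - 1))
        for f, (tr, va) in enumerate(_stratified_folds(surv.event, k, rep_seed)):
            if surv.event[va].sum() == 0:
                raise ValueError("validation fold contains zero events")
            model = fit_model(model_kind, df.iloc[tr], surv.subset(tr),
                              seed=rep_seed + f, **model_kwargs)
            risk = model.predict(df.iloc[va])
            out[rep, f] = concordance(risk, surv.subset(va))
    return CVSummary(fold_cindex=out, k=k, reps=reps, seed=seed)


def sweep_kf(
    x_selected,
    surv: SurvivalData,
    k_s: int = 3,
    kf_values: tuple[int, ...] = tuple(range(2, 11)),
    model_kinds: tuple[str, ...] = MODEL_KINDS,
    k: int = 3,
    reps: int = 10,
    seed: int = 0,
    refit_per_fold: bool = True,
    trifactor_opts: dict | None = None,
    rsf_trees: int = 500,
) -> pd.DataFrame:
    """Meta-feature dimension sweep: CV concordance per (K_f, model).

    For every K_f the tri-factorization is, by default, refit on each
    training fold and held-out patients are projected by nonnegative least
    squares against the fold's fixed S and Y (fold-honest).  Setting
    ``refit_per_fold=False`` factorizes once on all patients before CV — the
    optimistic variant, retained for comparison.  Returns a tidy frame with
    columns (kf, model, rep, fold, cindex).
    """
    from .containers import FeatureMatrix

    if isinstance(x_selected, FeatureMatrix):
        xv = x_selected.values
    else:
        xv = np.asarray(x_selected, dtype=float)
    opts = {"max_iter": 200, "tol": 1e-6, "n_restarts": 2}
    if trifactor_opts:
        opts.update(trifactor_opts)
    rows = []
    for kf_dim in kf_values:
        full_fit = None
        if not refit_per_fold:
            full_fit = trifactor.fit(xv, k_s, kf_dim, seed=seed, **opts)
            full_m = trifactor.meta_features(full_fit).M
        for rep in range(reps):
            rep_seed = int(np.random.default_rng([seed, kf_dim, rep]).integers(2**31 - 1))
            for f, (tr, va) in enumerate(_stratified_folds(surv.event, k, rep_seed)):
                if refit_per_fold:
                    fold_fit = trifactor.fit(xv[tr], k_s, kf_dim, seed=rep_seed + f, **opts)
                    m_tr = trifactor.meta_features(fold_fit).M
                    _, m_va = trifactor.project_patients(xv[va], fold_fit.S, fold_fit.Y)
                else:
                    m_tr, m_va = full_m[tr], full_m[va]
                for kind in model_kinds:
                    kw = {"n_trees": rsf_trees} if kind == "rsf" else {}
                    model = fit_model(kind, m_tr, surv.subset(tr), seed=rep_seed + f, **kw)
                    c = concordance(model.predict(m_va), surv.subset(va))
                    rows.append(
                        {"kf": kf_dim, "model": kind, "rep": rep, "fold": f, "cindex": c}
                    )
    return pd.DataFrame(rows)
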