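"""Reproducibility and redundancy feature selection.

Two-stage reduction of a raw radiomic feature table:

1. **Reproducibility** — features measured by two independent raters are kept
   only if their intraclass correlation coefficient exceeds a threshold
   (default 0.75, strict inequality).  The ICC form is ICC(2,1): two-way
   random effects, absolute agreement, single measurement — the standard
   choice for inter-observer segmentation-reproducibility studies.
2. **Redundancy** — within each modality (PET and CT separately), features
   are greedily removed until no within-modality pair of surviving features
   has |Pearson r| at or above the modality threshold (defaults 0.76 for
   PET, 0.40 for CT).  At each step the feature with the largest mean
   absolute correlation to the remaining same-modality features, among those
   still in a violating pair, is removed; ties go to the later column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import FeatureMatrix

__all__ = [
    "SelectionReport",
    "icc_2_1",
    "icc_per_feature",
    "filter_by_icc",
    "correlation_prune",
    "export_correlation_matrix",
    "select_features",
]


@dataclass
class SelectionReport:
    """Audit trail of a selection run."""

    icc_per_feature: dict[str, float] = field(default_factory=dict)
    kept_after_icc: list[str] = field(default_factory=list)
    #: dropped feature -> (retained partner with the highest |r|, that |r|)
    dropped_redundant: dict[str, tuple[str, float]] = field(default_factory=dict)
    dropped_zero_variance: list[str] = field(default_factory=list)
    final_features: list[str] = field(default_factory=list)


def _icc_2_1_from_matrix(y: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) over stacked subject x rater (x feature) arrays.

    ``y`` has shape (n, k) or (n, k, f).  The two-way random-effects ANOVA
    decomposition gives

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    if y.ndim == 2:
        y = y[:, :, None]
    n, k, _ = y.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    grand = y.mean(axis=(0, 1))
    row_mean = y.mean(axis=1)  # (n, f)
    col_mean = y.mean(axis=0)  # (k, f)
    ss_total = ((y - grand) ** 2).sum(axis=(0, 1))
    ss_rows = k * ((row_mean - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_mean - grand) ** 2).sum(axis=0)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msr - mse) / denom
    return icc


def icc_2_1(x1: np.ndarray, x2: np.ndarray) -> float:
    """ICC(2,1) agreement between two raters' measurements of one feature."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(x1) < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("inputs must be finite")
    y = np.stack([x1, x2], axis=1)
    if np.ptp(y) == 0:
        raise ValueError("ICC undefined for constant input across both raters")
    icc = float(_icc_2_1_from_matrix(y)[0])
    # numerical guard only; the estimator lies in [-1, 1] analytically for k=2
    return float(np.clip(icc, -1.0, 1.0))


def icc_per_feature(x1: FeatureMatrix, x2: FeatureMatrix) -> dict[str, float]:
    """ICC(2,1) for every feature column of a two-rater pair of tables."""
    if x1.shape != x2.shape or x1.feature_names != x2.feature_names:
        raise ValueError("rater tables must share shape and feature order")
    y = np.stack([x1.values, x2.values], axis=1)  # (n, 2, f)
    icc = np.clip(_icc_2_1_from_matrix(y), -1.0, 1.0)
    return dict(zip(x1.feature_names, icc.tolist()))


def filter_by_icc(
    x1: FeatureMatrix, x2: FeatureMatrix, threshold: float = 0.75
) -> SelectionReport:
    """Keep exactly the features whose ICC(2,1) is strictly above ``threshold``."""
    icc = icc_per_feature(x1, x2)
    report = SelectionReport(icc_per_feature=icc)
    report.kept_after_icc = [f for f in x1.feature_names if icc[f] > threshold]
    report.final_features = list(report.kept_after_icc)
    return report


def _prune_modality(
    corr: np.ndarray, names: list[str], threshold: float
) -> tuple[list[int], dict[str, tuple[str, float]]]:
    """Greedy removal until no pair has |r| >= threshold; returns kept indices."""
    m = corr.shape[0]
    alive = list(range(m))
    dropped: dict[str, tuple[str, float]] = {}
    while True:
        sub = np.abs(corr[np.ix_(alive, alive)])
        np.fill_diagonal(sub, 0.0)
        violating = sub >= threshold
        if not violating.any():
            break
        mean_abs = sub.mean(axis=1)
        in_pair = violating.any(axis=1)
        # candidates are members of a violating pair; argmax of mean |r|,
        # ties broken by the later original column index
        cand = [i for i in range(len(alive)) if in_pair[i]]
        best = max(cand, key=lambda i: (mean_abs[i], alive[i]))
        partner_local = int(np.argmax(sub[best]))
        dropped[names[alive[best]]] = (
            names[alive[partner_local]],
            float(sub[best, partner_local]),
        )
        del alive[best]
    return alive, dropped


def correlation_prune(
    x: FeatureMatrix, threshold_pet: float = 0.76, threshold_ct: float = 0.40
) -> SelectionReport:
    """Redundancy pruning within each modality at its own |r| threshold.

    Zero-variance columns (Pearson undefined) are dropped first and logged.
    """
    if x.n_patients < 2:
        raise ValueError("correlation requires at least 2 patients")
    report = SelectionReport()
    variances = x.values.var(axis=0)
    zero_var = [f for f, v in zip(x.feature_names, variances) if v == 0]
    report.dropped_zero_variance = zero_var

    kept: list[str] = []
    thresholds = {"PET": threshold_pet, "CT": threshold_ct}
    for tag, thr in thresholds.items():
        cols = [
            j
            for j, (name, mod) in enumerate(zip(x.feature_names, x.modality))
            if mod == tag and name not in zero_var
        ]
        if not cols:
            continue
        names = [x.feature_names[j] for j in cols]
        corr = np.corrcoef(x.values[:, cols], rowvar=False)
        corr = np.atleast_2d(corr)
        alive, dropped = _prune_modality(corr, names, thr)
        kept.extend(names[i] for i in alive)
        report.dropped_redundant.update(dropped)

    # preserve the original column order of the input table
    order = {f: j for j, f in enumerate(x.feature_names)}
    report.final_features = sorted(kept, key=order.__getitem__)
    return report


def export_correlation_matrix(x: FeatureMatrix) -> np.ndarray:
    """Full F x F Pearson correlation matrix (symmetric, unit diagonal)."""
    if np.any(x.values.var(axis=0) == 0):
        bad = [f for f, v in zip(x.feature_names, x.values.var(axis=0)) if v == 0]
        raise ValueError(f"zero-variance columns: {bad}")
    corr = np.corrcoef(x.values, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def select_features(
    x1: FeatureMatrix,
    x2: FeatureMatrix | None = None,
    icc_threshold: float = 0.75,
    threshold_pet: float = 0.76,
    threshold_ct: float = 0.40,
) -> SelectionReport:
    """Full two-stage selection: ICC filter (if a rater-2 table is given)
    followed by within-modality correlation pruning of the survivors."""
    if x2 is not None:
        report = filter_by_icc(x1, x2, threshold=icc_threshold)
        surviving = x1.select_features(report.kept_after_icc)
    else:
        report = SelectionReport()
        report.kept_after_icc = list(x1.feature_names)
        surviving = x1
    prune = correlation_prune(surviving, threshold_pet, threshold_ct)
    report.dropped_redundant = prune.dropped_redundant
    report.dropped_zero_variance = prune.dropped_zero_variance
    report.final_features = prune.final_features
    return report
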