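"""Risk-group stratification: Kaplan-Meier curves and log-rank tests.

Cluster labels (typically from the tri-factorization at K_s = 2 or 3) define
candidate risk groups; group survival is summarised by the product-limit
estimator and compared with the unweighted log-rank test, overall and for
every pair of groups.  Pairwise p-values are unadjusted by default (an
optional Bonferroni correction is available), matching the usual reporting
style for three-group survival comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .containers import SurvivalData

__all__ = ["KMCurve", "LogrankResult", "km_curve", "logrank", "pairwise_logrank", "km_median"]


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at distinct event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step interpolation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


@dataclass
class LogrankResult:
    chi_square: float
    p: float
    df: int


def km_curve(surv: SurvivalData) -> KMCurve:
    """Kaplan-Meier estimate; censored subjects leave the risk set after their time."""
    if len(surv) == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time_months, surv.event)
    table = kmf.event_table
    with_events = table[table["observed"] > 0]
    times = with_events.index.to_numpy(dtype=float)
    probs = np.array([kmf.predict(t) for t in times], dtype=float)
    return KMCurve(
        event_times=times,
        survival_prob=probs,
        at_risk=with_events["at_risk"].to_numpy(dtype=int),
        events=with_events["observed"].to_numpy(dtype=int),
    )


def km_median(surv: SurvivalData) -> float:
    """Median survival time (inf if the curve never reaches 0.5)."""
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time_months, surv.event)
    return float(kmf.median_survival_time_)


def logrank(surv: SurvivalData, labels: np.ndarray) -> LogrankResult:
    """Unweighted log-rank test across all groups (df = groups - 1)."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("log-rank requires at least two groups")
    if surv.n_events == 0:
        raise ValueError("log-rank requires at least one event")
    res = multivariate_logrank_test(surv.time_months, labels, surv.event)
    return LogrankResult(
        chi_square=float(res.test_statistic),
        p=float(res.p_value),
        df=len(groups) - 1,
    )


def pairwise_logrank(
    surv: SurvivalData, labels: np.ndarray, bonferroni: bool = False
) -> pd.DataFrame:
    """Log-rank p-value for every pair of groups.

    Returns a symmetric groups x groups table with NaN on the diagonal.
    P-values are raw unless ``bonferroni`` is set, in which case they are
    multiplied by the number of pairs (capped at 1).
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("pairwise log-rank requires at least two groups")
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = pd.DataFrame(np.nan, index=groups, columns=groups)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            mask = np.isin(labels, (g1, g2))
            sub = surv.subset(np.where(mask)[0])
            p = logrank(sub, labels[mask]).p
            if bonferroni:
                p = min(1.0, p * n_pairs)
            out.loc[g1, g2] = out.loc[g2, g1] = p
    return out
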