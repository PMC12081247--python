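"""Independent brute-force oracles used to validate the statistical kernels.

Everything here is deliberately written the slow, literal way (explicit
loops over subjects, risk sets and pairs) so that agreement with the
package's vectorized / library-backed implementations is meaningful.
"""

from __future__ import annotations

import numpy as np


def icc_2_1_anova(x1, x2) -> float:
    """ICC(2,1) from the two-way ANOVA mean squares, written out longhand."""
    y = np.column_stack([np.asarray(x1, float), np.asarray(x2, float)])
    n, k = y.shape
    grand = y.mean()
    ss_rows = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    icc = (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )
    # the estimator is reported on [-1, 1]; the raw ratio can drop below -1
    # for k = 2 when the raters disagree catastrophically
    return float(min(max(icc, -1.0), 1.0))


def km_product_limit(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Hand-rolled product-limit estimator at distinct event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    event_times = np.unique(time[event == 1])
    s = 1.0
    probs = []
    for t in event_times:
        at_risk = np.sum(time >= t)
        deaths = np.sum((time == t) & (event == 1))
        s *= 1.0 - deaths / at_risk
        probs.append(s)
    return event_times, np.asarray(probs)


def logrank_statistic(time, event, labels) -> float:
    """Multi-group log-rank chi-square from explicit risk-table tabulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    g = len(groups)
    observed = np.zeros(g)
    expected = np.zeros(g)
    var = np.zeros((g, g))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = ((time == t) & (event == 1)).sum()
        for a, ga in enumerate(groups):
            n_a = (at_risk & (labels == ga)).sum()
            observed[a] += ((time == t) & (event == 1) & (labels == ga)).sum()
            expected[a] += d_t * n_a / n_t
            for b, gb in enumerate(groups):
                n_b = (at_risk & (labels == gb)).sum()
                same = 1.0 if a == b else 0.0
                if n_t > 1:
                    var[a, b] += (
                        d_t * (n_a / n_t) * (same - n_b / n_t) * (n_t - d_t) / (n_t - 1)
                    )
    diff = (observed - expected)[:-1]
    vinv = np.linalg.pinv(var[:-1, :-1])
    return float(diff @ vinv @ diff)


def harrell_c_pairs(risk, time, event) -> float:
    """Harrell's C by exhaustive ordered-pair enumeration.

    Comparable pairs: strictly shorter time with an event, or tied times
    where exactly one subject has the event (the event is treated as
    occurring first).  Tied risk scores score 1/2.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (time[i] < time[j] and event[i] == 1) or (
                time[i] == time[j] and event[i] == 1 and event[j] == 0
            )
            if not comparable:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def greedy_prune_reference(corr: np.ndarray, threshold: float) -> list[int]:
    """Reference implementation of the redundancy-pruning order.

    Repeatedly drops the member of a violating pair with the largest mean
    absolute correlation to the remaining features (ties -> later index)
    until no pair reaches the threshold.  Returns surviving indices.
    """
    alive = list(range(corr.shape[0]))
    while True:
        sub = np.abs(corr[np.ix_(alive, alive)]).astype(float)
        np.fill_diagonal(sub, 0.0)
        pairs = [
            (i, j)
            for i in range(len(alive))
            for j in range(i + 1, len(alive))
            if sub[i, j] >= threshold
        ]
        if not pairs:
            return alive
        in_pair = sorted({i for p in pairs for i in p})
        means = sub.mean(axis=1)
        best = max(in_pair, key=lambda i: (means[i], alive[i]))
        alive.pop(best)
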