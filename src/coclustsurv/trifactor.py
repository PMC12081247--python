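"""Orthogonality-constrained non-negative matrix tri-factorization.

Two-way (co-)clustering of a nonnegative patients x features matrix
``X (N x F)`` by the factorization

    min_{A,S,Y} ||X - A S Y||_F^2
    s.t.  A >= 0, S >= 0, Y >= 0,  A^T A = I,  Y Y^T = I

where ``A (N x K_s)`` encodes membership of K_s patient sub-clusters,
``Y (K_f x F)`` encodes membership of K_f feature sub-clusters, and
``S (K_s x K_f)`` carries the scales and cluster-cluster interactions.
The ``N x K_f`` meta-feature matrix ``M = A S`` is the low-dimensional
representation used for survival modelling.

Optimization is alternating multiplicative updates.  Each factor is updated
by an elementwise multiply-by-ratio rule derived from the KKT conditions of
the orthogonality-constrained problem (the square-root ratio family):

    A <- A * sqrt( (X Y^T S^T)   / (A A^T X Y^T S^T) )
    Yt <- Yt * sqrt( (X^T A S)   / (Yt Y X^T A S) )        (Yt = Y^T)
    S <- S * sqrt( (A^T X Y^T)  / (A^T A S Y Y^T) )

These rules preserve nonnegativity and fold the orthogonality constraints
into the A and Y updates; orthogonality is therefore enforced softly and the
residuals ``||A^T A - I||_F`` and ``||Y Y^T - I||_F`` are reported as
diagnostics (exact nonnegative orthogonal factors are indicator-like and
generally unattainable on noisy data).  Because the square-root rules descend
an auxiliary function rather than the raw objective, each sweep is
safeguarded: if a sweep fails to decrease ``||X - ASY||_F^2`` the iterate is
rolled back and a plain (provably monotone) multiplicative sweep without the
orthogonality coupling is taken instead; if that also yields no descent the
run stops.  The recorded objective trajectory is therefore non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .containers import FeatureMatrix

__all__ = [
    "TriFactorOutput",
    "MetaFeatureMatrix",
    "rescale_nonnegative",
    "objective",
    "fit",
    "meta_features",
    "assign_patient_clusters",
    "assign_feature_clusters",
    "project_patients",
]

_EPS = 1e-12


@dataclass
class TriFactorOutput:
    """Result of one tri-factorization fit (best restart)."""

    A: np.ndarray
    S: np.ndarray
    Y: np.ndarray
    k_s: int
    k_f: int
    objective_trajectory: np.ndarray
    orthogonality_residuals: tuple[float, float]
    seed_used: int
    n_restarts: int
    converged: bool
    patient_ids: list[str] | None = None
    feature_names: list[str] | None = None


@dataclass
class MetaFeatureMatrix:
    """The N x K_f meta-feature matrix M = A S."""

    M: np.ndarray
    patient_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if np.any(self.M < 0):
            raise ValueError("meta-features must be nonnegative")


def rescale_nonnegative(
    x: FeatureMatrix, return_params: bool = False
) -> FeatureMatrix | tuple[FeatureMatrix, dict[str, np.ndarray]]:
    """Per-feature min-max rescaling to [0, 1].

    The factorization model requires an X approximable by nonnegative
    factors; radiomic features (e.g. skewness) can be negative, so each
    column is affinely mapped to [0, 1].  Constant columns map to all-zeros.
    The affine parameters (per-column minimum and range) are returned on
    request for reporting / inverse mapping.
    """
    vals = x.values
    lo = vals.min(axis=0)
    rng = np.ptp(vals, axis=0)
    safe = np.where(rng > 0, rng, 1.0)
    scaled = (vals - lo) / safe
    scaled[:, rng == 0] = 0.0
    out = FeatureMatrix(scaled, list(x.patient_ids), list(x.feature_names), list(x.modality))
    if return_params:
        return out, {"min": lo, "range": rng}
    return out


def objective(x: np.ndarray, a: np.ndarray, s: np.ndarray, y: np.ndarray) -> float:
    """Squared Frobenius reconstruction error ||X - A S Y||_F^2."""
    resid = x - a @ s @ y
    return float(np.sum(resid * resid))


def _orthogonal_sweep(x, a, s, y):
    yt = y.T
    a = a * np.sqrt((x @ yt @ s.T) / (a @ (a.T @ x @ yt @ s.T) + _EPS))
    yt = yt * np.sqrt((x.T @ a @ s) / (yt @ (yt.T @ (x.T @ a @ s)) + _EPS))
    y = yt.T
    s = s * np.sqrt((a.T @ x @ y.T) / (a.T @ a @ s @ y @ y.T + _EPS))
    return a, s, y


def _plain_sweep(x, a, s, y):
    w = s @ y
    a = a * (x @ w.T) / (a @ w @ w.T + _EPS)
    h = a @ s
    y = y * (h.T @ x) / (h.T @ h @ y + _EPS)
    s = s * (a.T @ x @ y.T) / (a.T @ a @ s @ y @ y.T + _EPS)
    return a, s, y


def _init_factors(x, k_s, k_f, rng):
    """Clustering-seeded initialization.

    Restarts differ through the seeding of two k-means runs (rows -> A,
    columns -> Y).  Indicator matrices are column-normalised (so A^T A = I
    and Y Y^T = I exactly at the start), floored at a small positive value to
    keep the multiplicative updates alive, and S is set to the least-squares
    coupling A^T X Y^T.  Purely random nonnegative initializations leave the
    orthogonality constraints no basin to act in: with k_f above the rank of
    the signal the reconstruction error alone does not identify the block
    structure, and label recovery fails.
    """
    from sklearn.cluster import KMeans

    n, f = x.shape
    seed_a, seed_y = (int(v) for v in rng.integers(0, 2**31 - 1, size=2))
    rows = KMeans(k_s, n_init=4, random_state=seed_a).fit_predict(x)
    cols = KMeans(k_f, n_init=4, random_state=seed_y).fit_predict(x.T)
    a = np.zeros((n, k_s))
    a[np.arange(n), rows] = 1.0
    yt = np.zeros((f, k_f))
    yt[np.arange(f), cols] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        a /= np.sqrt(np.maximum(a.sum(axis=0, keepdims=True), 1.0))
        yt /= np.sqrt(np.maximum(yt.sum(axis=0, keepdims=True), 1.0))
    a += 1e-3
    yt += 1e-3
    s = np.maximum(a.T @ x @ yt, _EPS)
    return a, s, yt.T


def _canonicalize(a, s, y):
    """Fix the factorization's permutation symmetry deterministically.

    Components of A (and of Y) are ordered by ascending mass (column / row
    sum, stable sort).  Besides reproducibility, this places empty or dead
    components first, so degenerate all-zero patient rows — whose argmax is
    index 0 by the tie rule — land on the massless component instead of
    colliding with a populated cluster.
    """
    oa = np.argsort(a.sum(axis=0), kind="stable")
    a, s = a[:, oa], s[oa, :]
    oy = np.argsort(y.sum(axis=1), kind="stable")
    y, s = y[oy, :], s[:, oy]
    return a, s, y


def _run_once(x, k_s, k_f, max_iter, tol, rng):
    a, s, y = _init_factors(x, k_s, k_f, rng)
    obj = objective(x, a, s, y)
    trajectory = [obj]
    converged = False
    for _ in range(max_iter):
        a2, s2, y2 = _orthogonal_sweep(x, a, s, y)
        obj2 = objective(x, a2, s2, y2)
        if obj2 > obj * (1.0 + 1e-9):
            # square-root rules descend an auxiliary function, not the raw
            # objective; fall back to the provably monotone plain sweep
            a2, s2, y2 = _plain_sweep(x, a, s, y)
            obj2 = objective(x, a2, s2, y2)
            if obj2 > obj * (1.0 + 1e-9):
                converged = True  # no descent move left; keep the iterate
                break
        a, s, y, prev = a2, s2, y2, obj
        obj = obj2
        trajectory.append(obj)
        if abs(prev - obj) <= tol * max(prev, _EPS):
            converged = True
            break
    return a, s, y, np.asarray(trajectory), converged


def fit(
    x: FeatureMatrix | np.ndarray,
    k_s: int,
    k_f: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 10,
    seed: int = 0,
) -> TriFactorOutput:
    """Fit the tri-factorization; return the best of ``n_restarts`` runs.

    Each restart is independently seeded (sub-streams of ``seed``) and
    initialized from a pair of k-means clusterings of the rows and columns
    of X (see ``_init_factors``).  A run stops when the relative objective
    change drops below ``tol`` or after ``max_iter`` sweeps; the restart with
    the lowest final objective is returned, with components in the canonical
    ascending-mass order.
    """
    if isinstance(x, FeatureMatrix):
        values = x.values
        pids: list[str] | None = list(x.patient_ids)
        fnames: list[str] | None = list(x.feature_names)
    else:
        values = np.asarray(x, dtype=float)
        pids = fnames = None
    n, f = values.shape
    if not 2 <= k_s <= n:
        raise ValueError(f"k_s must lie in [2, {n}]")
    if not 2 <= k_f <= f:
        raise ValueError(f"k_f must lie in [2, {f}]")
    if np.any(values < 0):
        raise ValueError("X must be nonnegative; apply rescale_nonnegative first")
    if not np.any(values):
        raise ValueError("X is identically zero")
    if n_restarts < 1:
        raise ValueError("n_restarts must be positive")

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        a, s, y, traj, conv = _run_once(values, k_s, k_f, max_iter, tol, rng)
        # replace the incumbent only on a relative improvement: at a shared
        # optimum the final objectives differ only by rounding noise and the
        # earliest restart must win deterministically
        if best is None or traj[-1] < best[3][-1] * (1.0 - 1e-6):
            best = (a, s, y, traj, conv)
    a, s, y, traj, conv = best
    a, s, y = _canonicalize(a, s, y)
    ra = float(np.linalg.norm(a.T @ a - np.eye(k_s)))
    ry = float(np.linalg.norm(y @ y.T - np.eye(k_f)))
    return TriFactorOutput(
        A=a,
        S=s,
        Y=y,
        k_s=k_s,
        k_f=k_f,
        objective_trajectory=traj,
        orthogonality_residuals=(ra, ry),
        seed_used=seed,
        n_restarts=n_restarts,
        converged=conv,
        patient_ids=pids,
        feature_names=fnames,
    )


def meta_features(out: TriFactorOutput) -> MetaFeatureMatrix:
    """Meta-features M = A S (one row per patient, one column per feature group)."""
    return MetaFeatureMatrix(out.A @ out.S, out.patient_ids)


def assign_patient_clusters(out: TriFactorOutput) -> np.ndarray:
    """Patient label = index of each row's maximum in A (ties -> lowest index)."""
    return np.argmax(out.A, axis=1)


def assign_feature_clusters(out: TriFactorOutput) -> np.ndarray:
    """Feature label = index of each column's maximum in Y (ties -> lowest index)."""
    return np.argmax(out.Y, axis=0)


def project_patients(
    x_new: np.ndarray, s: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fold new patients into a fitted factorization.

    With ``S`` and ``Y`` fixed from a training fit, each new patient's
    membership row ``a`` solves the nonnegative least-squares problem
    ``min_{a>=0} ||x - a (S Y)||_2``; the patient's meta-features are then
    ``a S``.  Returns ``(A_new, M_new)``.
    """
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    basis = (s @ y).T  # (F, k_s)
    a_new = np.empty((x_new.shape[0], s.shape[0]))
    for i, row in enumerate(x_new):
        a_new[i], _ = nnls(basis, row)
    return a_new, a_new @ s
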