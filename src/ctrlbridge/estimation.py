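"""Estimation of the resting-state dynamics and task states from ROI time series.

The pipeline follows the usual route for fitting a continuous-time linear
stochastic model to regularly sampled multivariate data:

1.  per-subject trace normalization — each subject's series is divided by
    the square root of the trace of its reference-segment covariance (the
    resting run, or the task-free moments of a task run), so that series
    from different subjects can be concatenated;
2.  a sparse VAR(1) fit  x(t+dt) = a x(t) + b + eps  by row-wise lasso
    (ordinary least squares when the penalty is zero), with regression
    pairs never spanning a concatenation boundary;
3.  conversion to continuous time:  A = log(a)/dt  (principal matrix
    logarithm) and

        S_C = -(1/dt) vec^-1[(I - a (x) a)^-1 log(a (x) a) vec(S_eps)],

    which inverts the exact discrete-continuous moment identity, so a
    noiseless round trip through the exact discretization is exact.

Task states are estimated as: mean = mean(task-performing) minus
mean(task-free), covariance = covariance of the task-performing moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence
import warnings

import numpy as np
from scipy.linalg import logm, solve_discrete_lyapunov
from sklearn.linear_model import Lasso

from .exceptions import (
    BranchError,
    InsufficientDataError,
    InvalidArgumentError,
    LabelingError,
    NonStationaryError,
)
from .linsde import GaussianState, LinearSystem, symmetrize

__all__ = [
    "TimeSeriesData",
    "VarFit",
    "trace_normalize",
    "fit_var_lasso",
    "select_lambda_cv",
    "to_continuous_system",
    "estimate_rest_state",
    "estimate_task_state",
    "bootstrap_concatenate",
    "shrink_to_diagonal",
    "task_activation_tvalues",
]

REST = "rest"
TASK_PERFORMING = "task_performing"
TASK_FREE = "task_free"


@dataclass(frozen=True)
class TimeSeriesData:
    """ROI-by-time data block: values (timepoints x n), sampling interval, labels.

    ``segment_starts`` marks the first row of each concatenated segment so
    that lagged regression pairs never straddle two subjects/runs.
    """

    values: np.ndarray
    dt: float
    labels: np.ndarray | None = None
    subject_id: str = ""
    roi_names: tuple[str, ...] | None = None
    segment_starts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.isfinite(v).all():
            raise InvalidArgumentError("time series contains non-finite values")
        if v.shape[0] < 2:
            raise InvalidArgumentError("need at least 2 timepoints")
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise InvalidArgumentError("dt must be finite and > 0")
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape != (v.shape[0],):
                raise InvalidArgumentError("labels length must equal the number of timepoints")
            object.__setattr__(self, "labels", lab)
        seg = self.segment_starts
        seg = np.array([0]) if seg is None else np.asarray(seg, dtype=int)
        if seg[0] != 0 or (np.diff(seg) <= 0).any() or seg[-1] >= v.shape[0]:
            raise InvalidArgumentError("segment_starts must begin at 0 and increase")
        names = self.roi_names
        if names is not None:
            names = tuple(str(s) for s in names)
            if len(names) != v.shape[1]:
                raise InvalidArgumentError("roi_names length must equal the number of ROIs")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "segment_starts", seg)
        object.__setattr__(self, "roi_names", names)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def segment_bounds(self) -> list[tuple[int, int]]:
        starts = list(self.segment_starts) + [self.n_timepoints]
        return [(int(a), int(b)) for a, b in zip(starts[:-1], starts[1:])]


@dataclass(frozen=True)
class VarFit:
    """Discrete VAR(1) fit: x(t+dt) = a_hat x(t) + intercept + eps."""

    a_hat: np.ndarray
    intercept: np.ndarray
    S_eps: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        S = np.asarray(self.S_eps, dtype=float)
        if np.linalg.norm(S - S.T) > 1e-10 * max(np.linalg.norm(S), 1e-300):
            raise InvalidArgumentError("S_eps must be symmetric")
        object.__setattr__(self, "a_hat", np.asarray(self.a_hat, dtype=float))
        object.__setattr__(self, "intercept", np.asarray(self.intercept, dtype=float))
        object.__setattr__(self, "S_eps", 0.5 * (S + S.T))
        if self.lam < 0:
            raise InvalidArgumentError("lambda must be >= 0")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _reference_rows(series: TimeSeriesData, reference_label: str | None) -> np.ndarray:
    if series.labels is None or reference_label is None:
        return series.values
    mask = series.labels == reference_label
    if not mask.any():
        raise LabelingError(f"no timepoints labeled {reference_label!r}")
    return series.values[mask]


def trace_normalize(series: TimeSeriesData, reference_label: str | None = None) -> TimeSeriesData:
    """Scale the whole series so the reference segment's covariance has trace 1.

    The reference segment is the rows carrying ``reference_label`` (e.g. the
    task-free moments), or the whole series when no label is given.
    """
    ref = _reference_rows(series, reference_label)
    if ref.shape[0] < series.n + 1:
        raise InsufficientDataError(
            f"reference segment has {ref.shape[0]} timepoints; need at least n+1 = {series.n + 1}"
        )
    tr = float(np.trace(np.atleast_2d(np.cov(ref.T))))
    if tr <= 0:
        raise InvalidArgumentError("reference covariance trace is not positive")
    return TimeSeriesData(
        series.values / np.sqrt(tr),
        series.dt,
        series.labels,
        series.subject_id,
        series.roi_names,
        series.segment_starts,
    )


# ---------------------------------------------------------------------------
# VAR(1) fit
# ---------------------------------------------------------------------------

def _lagged_pairs(series: TimeSeriesData) -> tuple[np.ndarray, np.ndarray]:
    Xs, Ys = [], []
    for a, b in series.segment_bounds():
        if b - a >= 2:
            Xs.append(series.values[a:b - 1])
            Ys.append(series.values[a + 1:b])
    if not Xs:
        raise InsufficientDataError("no segment long enough for lagged pairs")
    return np.vstack(Xs), np.vstack(Ys)


def fit_var_lasso(series: TimeSeriesData, lam: float = 0.0) -> VarFit:
    """Row-wise L1-penalized VAR(1) regression of x(t+dt) on x(t).

    ``lam`` is the lasso penalty in scikit-learn's convention
    (1/(2N) ||y - Xw||^2 + lam ||w||_1); ``lam = 0`` gives ordinary least
    squares.  Residual covariance is the empirical second moment of the
    one-step-ahead residuals.
    """
    if lam < 0:
        raise InvalidArgumentError("lambda must be >= 0")
    X, Y = _lagged_pairs(series)
    N, n = X.shape
    if N < 10 * n:
        warnings.warn(
            f"only {N} regression pairs for n={n} ROIs; fit may be unstable", UserWarning
        )
    if lam == 0.0:
        Xd = np.hstack([X, np.ones((N, 1))])
        if np.linalg.matrix_rank(Xd) < n + 1:
            raise np.linalg.LinAlgError("design matrix is rank deficient with lambda = 0")
        coef, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
        a_hat = coef[:-1].T
        intercept = coef[-1]
    else:
        model = Lasso(alpha=lam, fit_intercept=True, max_iter=50_000, tol=1e-8)
        a_hat = np.empty((n, n))
        intercept = np.empty(n)
        for k in range(n):
            model.fit(X, Y[:, k])
            a_hat[k] = model.coef_
            intercept[k] = model.intercept_
    resid = Y - X @ a_hat.T - intercept
    S_eps = symmetrize(resid.T @ resid / N, warn_tol=np.inf)
    return VarFit(a_hat, intercept, S_eps, lam)


def select_lambda_cv(series: TimeSeriesData, lambdas: Sequence[float] | None = None,
                     n_folds: int = 5, seed: int = 0) -> float:
    """Pick the lasso penalty by K-fold cross-validated one-step-ahead error.

    Folds partition the regression pairs; candidates default to a small
    logarithmic grid (including values near the OLS limit).
    """
    X, Y = _lagged_pairs(series)
    N = X.shape[0]
    if lambdas is None:
        lam_max = np.abs(X.T @ Y).max() / N
        lambdas = np.geomspace(lam_max, lam_max * 1e-4, 8)
    rng = np.random.default_rng(seed)
    order = rng.permutation(N)
    folds = np.array_split(order, n_folds)
    errs = np.zeros(len(lambdas))
    for j, lam in enumerate(lambdas):
        model = Lasso(alpha=lam, fit_intercept=True, max_iter=20_000, tol=1e-6)
        for holdout in folds:
            mask = np.ones(N, dtype=bool)
            mask[holdout] = False
            pred = np.empty((holdout.size, Y.shape[1]))
            for k in range(Y.shape[1]):
                model.fit(X[mask], Y[mask][:, k])
                pred[:, k] = model.predict(X[holdout])
            errs[j] += float(((Y[holdout] - pred) ** 2).sum())
    return float(lambdas[int(np.argmin(errs))])


# ---------------------------------------------------------------------------
# continuous-time conversion
# ---------------------------------------------------------------------------

def to_continuous_system(fit: VarFit, dt: float) -> LinearSystem:
    """Convert a VAR(1) fit to the continuous system (A, S_C).

    A = log(a)/dt (principal matrix logarithm).  S_C inverts the exact
    one-step noise integral using log(a (x) a) = L (x) I + I (x) L, so the
    n^2 x n^2 Kronecker system reduces to a discrete Lyapunov solve:

        S_C = -(1/dt) W,   W - a W a^T = L S_eps + S_eps L^T,  L = log(a).
    """
    if not np.isfinite(dt) or dt <= 0:
        raise InvalidArgumentError("dt must be finite and > 0")
    a = fit.a_hat
    lam_a = np.linalg.eigvals(a)
    if (np.abs(lam_a) >= 1.0).any():
        raise NonStationaryError(
            f"discrete coefficient has eigenvalue of modulus {np.abs(lam_a).max():.4f} >= 1"
        )
    if ((lam_a.real <= 0) & (np.abs(lam_a.imag) < 1e-12)).any():
        raise BranchError(
            "eigenvalue of a_hat on the closed negative real axis; "
            "the principal logarithm is not real — use a smaller sampling interval"
        )
    L = logm(a)
    if np.iscomplexobj(L):
        if np.abs(L.imag).max() > 1e-6:
            raise BranchError(
                "matrix logarithm has imaginary residual "
                f"{np.abs(L.imag).max():.2e} > 1e-6; use a smaller sampling interval"
            )
        L = L.real
    A = L / dt
    R = L @ fit.S_eps + fit.S_eps @ L.T
    W = solve_discrete_lyapunov(a, R)
    S_C = symmetrize(-W / dt, warn_tol=np.inf)
    # With noisy finite-sample inputs the implied S_C can leave the PD cone
    # even though the true noise rate is PD; project onto it.
    w, V = np.linalg.eigh(S_C)
    floor = 1e-6 * w[-1]
    if w[-1] <= 0:
        raise InvalidArgumentError("implied noise covariance rate is not positive")
    if w[0] < floor:
        warnings.warn(
            f"implied S_C had eigenvalues below {floor:.3e}; projected onto the PD cone",
            UserWarning,
        )
        S_C = (V * np.maximum(w, floor)) @ V.T
    return LinearSystem(A, S_C)


def match_rest_covariance(system: LinearSystem, sigma_rest: np.ndarray) -> LinearSystem:
    """Replace S_C so the fitted dynamics' steady state equals ``sigma_rest`` exactly.

    Solves the stationarity condition A Sigma + Sigma A^T + S_C = 0 for S_C
    given the empirical rest covariance; the result is projected onto the PD
    cone if sampling noise pushes it outside.  Off by default in the
    analysis pipeline — the empirical residual covariance is normally kept.
    """
    sigma_rest = 0.5 * (np.asarray(sigma_rest, dtype=float)
                        + np.asarray(sigma_rest, dtype=float).T)
    S_C = -(system.A @ sigma_rest + sigma_rest @ system.A.T)
    S_C = 0.5 * (S_C + S_C.T)
    w, V = np.linalg.eigh(S_C)
    if w[-1] <= 0:
        raise InvalidArgumentError(
            "rest covariance is incompatible with the fitted drift (implied S_C <= 0)"
        )
    floor = 1e-6 * w[-1]
    if w[0] < floor:
        warnings.warn(
            "implied S_C from the rest covariance was not PD; projected onto the PD cone",
            UserWarning,
        )
        S_C = (V * np.maximum(w, floor)) @ V.T
    return LinearSystem(system.A, S_C)


# ---------------------------------------------------------------------------
# state estimation
# ---------------------------------------------------------------------------

def shrink_to_diagonal(sigma: np.ndarray, max_cond: float = 1e8) -> np.ndarray:
    """Convex shrinkage toward the diagonal until the condition number is bounded.

    Returns (1-g) Sigma + g diag(Sigma) with the smallest g in [0, 1] (by
    bisection) achieving cond <= max_cond; used to make empirical
    covariances safe as bridge marginals.
    """
    sigma = 0.5 * (sigma + np.asarray(sigma).T)
    D = np.diag(np.clip(np.diag(sigma), 1e-12 * max(np.trace(sigma), 1e-300), None))

    def cond_ok(g):
        w = np.linalg.eigvalsh((1 - g) * sigma + g * D)
        return w[0] > 0 and w[-1] / w[0] <= max_cond

    if cond_ok(0.0):
        return sigma
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if cond_ok(mid):
            hi = mid
        else:
            lo = mid
    return (1 - hi) * sigma + hi * D


def estimate_rest_state(series: TimeSeriesData) -> GaussianState:
    """Empirical mean and covariance of the resting data (rest-labeled rows if present)."""
    rows = series.values if series.labels is None else series.values[series.labels == REST]
    if rows.shape[0] == 0 and series.labels is not None:
        rows = series.values
    if rows.shape[0] < 2:
        raise InsufficientDataError("need at least 2 timepoints to estimate moments")
    mu = rows.mean(axis=0)
    sigma = np.cov(rows.T).reshape(series.n, series.n)
    if np.linalg.eigvalsh(sigma)[-1] <= 0:
        warnings.warn("degenerate (zero) rest covariance", UserWarning)
    return GaussianState(mu, symmetrize(sigma, warn_tol=np.inf))


def estimate_task_state(series: TimeSeriesData) -> GaussianState:
    """Task state: mean(task-performing) - mean(task-free); covariance of task-performing."""
    if series.labels is None:
        raise LabelingError("task-state estimation requires block labels")
    perf = series.values[series.labels == TASK_PERFORMING]
    free = series.values[series.labels == TASK_FREE]
    if perf.shape[0] < 2 or free.shape[0] < 2:
        raise LabelingError("need both task_performing and task_free moments")
    mu = perf.mean(axis=0) - free.mean(axis=0)
    sigma = np.cov(perf.T).reshape(series.n, series.n)
    return GaussianState(mu, symmetrize(sigma, warn_tol=np.inf))


def task_activation_tvalues(series: TimeSeriesData) -> np.ndarray:
    """Per-ROI Welch t statistic, task-performing vs task-free moments."""
    if series.labels is None:
        raise LabelingError("activation t values require block labels")
    perf = series.values[series.labels == TASK_PERFORMING]
    free = series.values[series.labels == TASK_FREE]
    if perf.shape[0] < 2 or free.shape[0] < 2:
        raise LabelingError("need both task_performing and task_free moments")
    v1 = perf.var(axis=0, ddof=1) / perf.shape[0]
    v2 = free.var(axis=0, ddof=1) / free.shape[0]
    return (perf.mean(axis=0) - free.mean(axis=0)) / np.sqrt(v1 + v2)


# ---------------------------------------------------------------------------
# bootstrap concatenation
# ---------------------------------------------------------------------------

def concatenate_series(parts: Sequence[TimeSeriesData]) -> TimeSeriesData:
    """Concatenate blocks, recording segment boundaries so lagged pairs stay within blocks."""
    if not parts:
        raise InvalidArgumentError("nothing to concatenate")
    dt = parts[0].dt
    n = parts[0].n
    for p in parts:
        if p.dt != dt or p.n != n:
            raise InvalidArgumentError("all parts must share dt and ROI count")
    values = np.vstack([p.values for p in parts])
    has_labels = all(p.labels is not None for p in parts)
    labels = np.concatenate([p.labels for p in parts]) if has_labels else None
    starts, off = [], 0
    for p in parts:
        starts.extend((p.segment_starts + off).tolist())
        off += p.n_timepoints
    return TimeSeriesData(
        values, dt, labels,
        subject_id="+".join(p.subject_id for p in parts if p.subject_id),
        roi_names=parts[0].roi_names,
        segment_starts=np.asarray(starts, dtype=int),
    )


def bootstrap_concatenate(
    subjects: Sequence[TimeSeriesData],
    k: int,
    reps: int,
    seed: int,
    reference_label: str | None = None,
) -> Iterator[tuple[np.ndarray, TimeSeriesData]]:
    """Yield ``reps`` replicates of (chosen subject indices, concatenated series).

    Each replicate draws ``k`` subjects uniformly without replacement,
    trace-normalizes each against its reference segment, and concatenates
    them; the same seed reproduces identical replicates.
    """
    if k > len(subjects) or k < 1:
        raise InvalidArgumentError(f"k = {k} out of range for {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    for _ in range(int(reps)):
        idx = np.sort(rng.choice(len(subjects), size=k, replace=False))
        parts = [trace_normalize(subjects[i], reference_label) for i in idx]
        yield idx, concatenate_series(parts)
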