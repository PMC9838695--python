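"""Exact linear-algebra primitives for the uncontrolled Ornstein-Uhlenbeck system.

The uncontrolled brain dynamics are modelled as the linear stochastic
differential equation

    dx(t) = A x(t) dt + C dw(t),        x in R^n,

with drift matrix ``A`` (units 1/time) and noise covariance rate
``S_C = C C^T`` (signal^2 / time).  Everything downstream (bridge solving,
cost computation, VAR estimation) is built on the handful of exact
operations in this module: the transition matrix ``Phi(t) = exp(A t)``,
moment propagation, the stationary (Lyapunov) covariance, the
controllability Gramian ``M(T) = \\int_0^T Phi(T,s) S_C Phi(T,s)^T ds`` and
the exact one-step discretization of the process.

Time integrals are evaluated with the Van Loan block-matrix-exponential
construction, which is exact up to the accuracy of ``scipy.linalg.expm``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov

from .exceptions import (
    AsymmetryWarning,
    InvalidArgumentError,
    StabilityError,
)

__all__ = [
    "LinearSystem",
    "GaussianState",
    "transition_matrix",
    "steady_state",
    "propagate_uncontrolled",
    "gramian",
    "exact_discretization",
    "transition_and_gramian",
    "symmetrize",
    "sqrtm_pd",
]

_SYM_TOL = 1e-10
_ASYM_WARN = 1e-8


def symmetrize(X: np.ndarray, warn_tol: float = _ASYM_WARN) -> np.ndarray:
    """Return (X + X^T)/2, warning if the asymmetry is suspiciously large."""
    X = np.asarray(X, dtype=float)
    denom = max(np.linalg.norm(X), 1.0)
    if np.linalg.norm(X - X.T) > warn_tol * denom:
        warnings.warn(
            "matrix asymmetry exceeds %.0e relative; symmetrizing" % warn_tol,
            AsymmetryWarning,
            stacklevel=2,
        )
    return 0.5 * (X + X.T)


def sqrtm_pd(X: np.ndarray) -> np.ndarray:
    """Symmetric square root of a symmetric PSD matrix via eigendecomposition."""
    w, V = np.linalg.eigh(np.asarray(X, dtype=float))
    return (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T


@dataclass(frozen=True)
class LinearSystem:
    """Uncontrolled OU system dx = A x dt + C dw with S_C = C C^T.

    Parameters
    ----------
    A : (n, n) drift matrix, 1/time.
    S_C : (n, n) symmetric positive-definite noise covariance rate.
    """

    A: np.ndarray
    S_C: np.ndarray

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        S = np.atleast_2d(np.asarray(self.S_C, dtype=float))
        if A.shape[0] != A.shape[1] or A.shape != S.shape:
            raise InvalidArgumentError(
                f"A and S_C must be square with matching shape, got {A.shape} and {S.shape}"
            )
        if not (np.isfinite(A).all() and np.isfinite(S).all()):
            raise InvalidArgumentError("A and S_C must be finite")
        if np.linalg.norm(S - S.T) > _SYM_TOL * max(np.linalg.norm(S), 1e-300):
            raise InvalidArgumentError("S_C is not symmetric within 1e-10 relative")
        S = 0.5 * (S + S.T)
        w = np.linalg.eigvalsh(S)
        if w[0] <= 1e-12 * w[-1]:
            raise InvalidArgumentError(
                "S_C must be positive definite (noise covariance rate nonsingular); "
                f"eigenvalue ratio {w[0]:.3e}/{w[-1]:.3e}"
            )
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "S_C", S)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    # -- plain-text round trip -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "A": [float(v) for v in self.A.ravel()],
            "S_C": [float(v) for v in self.S_C.ravel()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearSystem":
        n = int(d["n"])
        return cls(
            A=np.asarray(d["A"], dtype=float).reshape(n, n),
            S_C=np.asarray(d["S_C"], dtype=float).reshape(n, n),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearSystem":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class GaussianState:
    """Mean vector and covariance matrix of a Gaussian brain-state distribution."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if sigma.shape != (mu.size, mu.size):
            raise InvalidArgumentError(
                f"sigma shape {sigma.shape} does not match mean length {mu.size}"
            )
        if not (np.isfinite(mu).all() and np.isfinite(sigma).all()):
            raise InvalidArgumentError("state moments must be finite")
        nrm = max(np.linalg.norm(sigma), 1e-300)
        if np.linalg.norm(sigma - sigma.T) > _SYM_TOL * nrm:
            raise InvalidArgumentError("sigma is not symmetric within 1e-10 relative")
        sigma = 0.5 * (sigma + sigma.T)
        w = np.linalg.eigvalsh(sigma)
        if w[0] < -1e-12 * max(abs(w[-1]), 1e-300):
            raise InvalidArgumentError(f"sigma is not PSD (min eigenvalue {w[0]:.3e})")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def n(self) -> int:
        return self.mu.size

    def is_pd(self, rel: float = 1e-10) -> bool:
        w = np.linalg.eigvalsh(self.sigma)
        return bool(w[0] > rel * max(w[-1], 0.0))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def transition_matrix(system: LinearSystem, dt: float) -> np.ndarray:
    """State transition matrix Phi(dt) = exp(A dt); dt may be zero or negative."""
    if not np.isfinite(dt):
        raise InvalidArgumentError("dt must be finite")
    return expm(system.A * float(dt))


def transition_and_gramian(system: LinearSystem, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (Phi(t), M(t)) with M(t) = int_0^t exp(A s) S_C exp(A^T s) ds.

    Uses the Van Loan block exponential

        exp(t [[A, S_C], [0, -A^T]]) = [[Phi, F12], [0, Phi^-T]],
        M(t) = F12 Phi^T,

    which is exact to expm accuracy; t >= 0.
    """
    if not np.isfinite(t) or t < 0:
        raise InvalidArgumentError("t must be finite and nonnegative")
    t = float(t)
    n = system.n
    # The block matrix contains -A^T, which is anti-stable for stable A; to
    # avoid overflow at large t the integral is built on a short base step
    # and doubled: M(2t) = Phi(t) M(t) Phi(t)^T + M(t).
    k = 0
    scale = np.linalg.norm(system.A, 2) * t
    if scale > 2.0:
        k = int(np.ceil(np.log2(scale / 2.0)))
    B = np.zeros((2 * n, 2 * n))
    B[:n, :n] = system.A
    B[:n, n:] = system.S_C
    B[n:, n:] = -system.A.T
    E = expm(B * (t / 2**k))
    Phi = E[:n, :n]
    M = E[:n, n:] @ Phi.T
    M = 0.5 * (M + M.T)
    for _ in range(k):
        M = Phi @ M @ Phi.T + M
        M = 0.5 * (M + M.T)
        Phi = Phi @ Phi
    return Phi, M


def _require_stable(system: LinearSystem, tol: float = -1e-10) -> None:
    lam = np.linalg.eigvals(system.A)
    worst = lam[np.argmax(lam.real)]
    if worst.real >= tol:
        raise StabilityError(
            f"drift matrix is not stable: eigenvalue {worst:.6g} has nonnegative real part"
        )


def steady_state(system: LinearSystem) -> GaussianState:
    """Stationary distribution N(0, Sigma) with A Sigma + Sigma A^T + S_C = 0."""
    _require_stable(system)
    Sigma = solve_continuous_lyapunov(system.A, -system.S_C)
    return GaussianState(np.zeros(system.n), symmetrize(Sigma))


def propagate_uncontrolled(system: LinearSystem, state: GaussianState, T: float) -> GaussianState:
    """Moments of x(T) under the uncontrolled flow started from ``state``.

    m_T = Phi(T) mu_0,  S_T = Phi(T) Sigma_0 Phi(T)^T + M(T).
    """
    if not np.isfinite(T) or T < 0:
        raise InvalidArgumentError("T must be finite and >= 0")
    if T == 0:
        return state
    Phi, M = transition_and_gramian(system, T)
    return GaussianState(Phi @ state.mu, symmetrize(Phi @ state.sigma @ Phi.T + M, warn_tol=np.inf))


def gramian(system: LinearSystem, T: float) -> np.ndarray:
    """Controllability Gramian M(T) = int_0^T Phi(T,s) S_C Phi(T,s)^T ds, T > 0."""
    if not np.isfinite(T) or T <= 0:
        raise InvalidArgumentError("T must be finite and > 0")
    return transition_and_gramian(system, T)[1]


def exact_discretization(system: LinearSystem, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact VAR(1) counterpart of the OU process at sampling interval dt.

    Returns (a, Sigma_dt) with a = exp(A dt) and
    Sigma_dt = int_0^dt exp(A s) S_C exp(A^T s) ds, so that
    x_{t+dt} = a x_t + eps, eps ~ N(0, Sigma_dt) has exactly the law of the
    continuous process on the sampling grid.
    """
    if not np.isfinite(dt) or dt <= 0:
        raise InvalidArgumentError("dt must be finite and > 0")
    return transition_and_gramian(system, dt)
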