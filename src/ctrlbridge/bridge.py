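"""Gaussian Schrödinger bridge under an Ornstein-Uhlenbeck prior.

Given the uncontrolled dynamics dx = A x dt + C dw and two Gaussian
marginals N(mu_0, Sigma_0) at t = 0 and N(mu_T, Sigma_T) at t = T, the
optimally controlled process (the one closest to the uncontrolled law in
path-space KL divergence) is again a linear diffusion

    dx = A x dt + v*(x, t) dt + C dw,
    v*(x, t) = -S_C (Pi(t) x - m(t)),          S_C = C C^T,

where the feedback potential Pi solves the matrix Riccati equation

    dPi/dt = -A^T Pi - Pi A + Pi S_C Pi,

the auxiliary (co-potential) H solves the same equation with the quadratic
term negated, and the controlled covariance is Sigma(t) = (Pi(t) + H(t))^-1
with the boundary coupling Pi + H = Sigma^-1 at both endpoints.

The minimal cost J* = E int_0^T ||v*||^2_{S_C^-1} dt (twice the path KL
divergence) splits exactly into a mean part and a covariance part:

    J_mean = (mu_T - Phi(T) mu_0)^T M(T)^-1 (mu_T - Phi(T) mu_0),
    J_cov  = int_0^T tr(S_C Pi) dt - [tr(Pi(T) Sigma_T) - tr(Pi(0) Sigma_0)],

with M(T) the controllability Gramian.  J_mean depends only on the marginal
means, J_cov only on the marginal covariances.

Solution strategy
-----------------
The boundary-coupled Riccati system is solved in closed form by reduction
to static entropic optimal transport between Gaussians: whitening the
prior transition kernel N(Phi x_0, M) turns the problem into the standard
Gaussian entropic-OT fixed point, whose solution is a symmetric matrix
square root.  The terminal potential Pi(T) obtained this way is then
propagated along its exact linear fractional flow

    Pi(t) = Phi(T,t)^T (I + Pi(T) M(t,T))^-1 Pi(T) Phi(T,t),

which remains valid when Pi(T) is singular (zero covariance cost).  The
boundary residuals are verified after the fact and a damped Newton polish
on Pi(T) is run only if they exceed tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json
import warnings

import numpy as np
from scipy.integrate import simpson
from scipy.linalg import expm
from scipy.optimize import root

from .exceptions import (
    ConditioningError,
    ConditioningWarning,
    ConsistencyError,
    ConvergenceError,
    InvalidArgumentError,
)
from .linsde import (
    GaussianState,
    LinearSystem,
    sqrtm_pd,
    symmetrize,
    transition_and_gramian,
)
from .reports import InputMap

__all__ = [
    "BridgeProblem",
    "BridgeSolution",
    "solve_covariance_bridge",
    "solve_bridge",
    "mean_cost",
    "covariance_cost",
    "total_cost",
    "mean_path_and_feedforward",
    "node_inputs",
]

_DEFAULT_INTERVALS = 200
_PD_REL = 1e-10


@dataclass(frozen=True)
class BridgeProblem:
    """A bridge between two Gaussian states over horizon T under an OU prior."""

    system: LinearSystem
    initial: GaussianState
    target: GaussianState
    horizon: float = 1.0
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.horizon) or self.horizon <= 0:
            raise InvalidArgumentError("horizon must be finite and > 0")
        n = self.system.n
        if self.initial.n != n or self.target.n != n:
            raise InvalidArgumentError("marginal dimension does not match the system")
        for name, st in (("initial", self.initial), ("target", self.target)):
            if not st.is_pd(_PD_REL):
                raise ConditioningError(f"{name} covariance must be positive definite")
        if self.grid is None:
            g = np.linspace(0.0, self.horizon, _DEFAULT_INTERVALS + 1)
        else:
            g = np.asarray(self.grid, dtype=float)
            if g.ndim != 1 or g.size < 51:
                raise InvalidArgumentError("grid must be 1-D with at least 51 points (K >= 50)")
            if not (np.all(np.diff(g) > 0) and abs(g[0]) < 1e-15 and
                    abs(g[-1] - self.horizon) < 1e-12 * max(self.horizon, 1.0)):
                raise InvalidArgumentError("grid must increase strictly from 0 to the horizon")
        object.__setattr__(self, "grid", g)

    def with_grid(self, n_intervals: int) -> "BridgeProblem":
        return BridgeProblem(
            self.system,
            self.initial,
            self.target,
            self.horizon,
            np.linspace(0.0, self.horizon, n_intervals + 1),
        )

    def to_dict(self) -> dict:
        return {
            "system": self.system.to_dict(),
            "mu0": self.initial.mu.tolist(),
            "sigma0": self.initial.sigma.ravel().tolist(),
            "muT": self.target.mu.tolist(),
            "sigmaT": self.target.sigma.ravel().tolist(),
            "horizon": self.horizon,
            "grid": self.grid.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BridgeProblem":
        sys_ = LinearSystem.from_dict(d["system"])
        n = sys_.n
        return cls(
            sys_,
            GaussianState(np.asarray(d["mu0"]), np.asarray(d["sigma0"]).reshape(n, n)),
            GaussianState(np.asarray(d["muT"]), np.asarray(d["sigmaT"]).reshape(n, n)),
            float(d["horizon"]),
            np.asarray(d["grid"], dtype=float) if d.get("grid") is not None else None,
        )


@dataclass
class BridgeSolution:
    """Time-gridded solution of the bridge plus the cost decomposition."""

    grid: np.ndarray
    Pi: np.ndarray          # (K+1, n, n)
    H: np.ndarray           # (K+1, n, n)
    Sigma_t: np.ndarray     # (K+1, n, n)
    mu_t: np.ndarray        # (K+1, n)
    m_t: np.ndarray         # (K+1, n)
    J_mean: float
    J_cov: float
    # cached kernel quantities on the same grid (implementation detail)
    Phi_t: np.ndarray = field(repr=False, default=None)    # Phi(t, 0)
    M_0t: np.ndarray = field(repr=False, default=None)     # Gramian over [0, t]
    PhiT_t: np.ndarray = field(repr=False, default=None)   # Phi(T, t)

    @property
    def J_total(self) -> float:
        return self.J_mean + self.J_cov

    @property
    def kl(self) -> float:
        """Path KL divergence between controlled and uncontrolled laws (= J_total / 2)."""
        return 0.5 * self.J_total

    def export(self, outdir: str | Path) -> None:
        """Write grid, Pi, Sigma, mu, m as TSV plus a JSON cost summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        K1, n, _ = self.Pi.shape
        np.savetxt(outdir / "grid.tsv", self.grid, delimiter="\t")
        np.savetxt(outdir / "Pi.tsv", self.Pi.reshape(K1, n * n), delimiter="\t")
        np.savetxt(outdir / "Sigma.tsv", self.Sigma_t.reshape(K1, n * n), delimiter="\t")
        np.savetxt(outdir / "mu.tsv", self.mu_t, delimiter="\t")
        np.savetxt(outdir / "m.tsv", self.m_t, delimiter="\t")
        (outdir / "costs.json").write_text(json.dumps({
            "J_mean": self.J_mean, "J_cov": self.J_cov,
            "J_total": self.J_total, "KL": self.kl,
        }, indent=1))


# ---------------------------------------------------------------------------
# covariance bridge (Pi, H, Sigma)
# ---------------------------------------------------------------------------

def _terminal_potential(system: LinearSystem, S0: np.ndarray, ST: np.ndarray,
                        Phi: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Closed-form Pi(T) via whitened Gaussian entropic optimal transport.

    With u_0 = G x_0 and u_T = G Phi^-1 x_T, G = (Phi^-1 M Phi^-T)^-1/2, the
    prior kernel becomes N(u_0, I); the static bridge coupling then solves
    W^2 + W = R S_T^ R with R = (S_0^)^1/2 (hats denote whitened marginals),
    and the conditional covariance V = R^-1 W R^-1 yields
    Pi(T) = Phi^-T G (V^-1 - I) G Phi^-1.
    """
    n = system.n
    Phii = np.linalg.inv(Phi)
    Mt = symmetrize(Phii @ M @ Phii.T, warn_tol=np.inf)
    G = np.linalg.inv(sqrtm_pd(Mt))
    S0h = symmetrize(G @ S0 @ G, warn_tol=np.inf)
    STh = symmetrize(G @ Phii @ ST @ Phii.T @ G, warn_tol=np.inf)
    R = sqrtm_pd(S0h)
    W = 0.5 * (sqrtm_pd(np.eye(n) + 4.0 * R @ STh @ R) - np.eye(n))
    Ri = np.linalg.inv(R)
    V = symmetrize(Ri @ W @ Ri, warn_tol=np.inf)
    wV = np.linalg.eigvalsh(V)
    if wV[0] <= 1e-14 * wV[-1]:
        raise ConditioningError("bridge conditional covariance is numerically singular")
    PiT = Phii.T @ G @ (np.linalg.inv(V) - np.eye(n)) @ G @ Phii
    return symmetrize(PiT, warn_tol=np.inf)


def _propagate_potentials(problem: BridgeProblem, PiT: np.ndarray):
    """Grid Pi, H, Sigma from the terminal potential via exact linear flows."""
    system = problem.system
    n = system.n
    ts = problem.grid
    T = problem.horizon
    K1 = ts.size
    eye = np.eye(n)

    Phi_t = np.empty((K1, n, n))
    M_0t = np.empty((K1, n, n))
    PhiT_t = np.empty((K1, n, n))
    for i, t in enumerate(ts):
        Phi_t[i], M_0t[i] = transition_and_gramian(system, t)
        PhiT_t[i] = expm(system.A * (T - t))
    M = M_0t[-1]

    Pi = np.empty((K1, n, n))
    for i in range(K1):
        MtT = symmetrize(M - PhiT_t[i] @ M_0t[i] @ PhiT_t[i].T, warn_tol=np.inf)
        X = np.linalg.solve(eye + PiT @ MtT, PiT)
        Pi[i] = symmetrize(PhiT_t[i].T @ X @ PhiT_t[i], warn_tol=np.inf)

    # H(t) follows the opposite-sign Riccati; its inverse flows linearly as
    # H(t)^-1 = Phi(t) H(0)^-1 Phi(t)^T + M(0,t).  The resolvent form below
    # avoids inverting H(0), which may be indefinite or singular (only
    # Pi + H = Sigma^-1 must be PD, not H itself).
    H0 = symmetrize(np.linalg.inv(problem.initial.sigma) - Pi[0], warn_tol=np.inf)
    H = np.empty_like(Pi)
    Sigma = np.empty_like(Pi)
    for i in range(K1):
        Phii = np.linalg.inv(Phi_t[i])
        Nt = symmetrize(Phii @ M_0t[i] @ Phii.T, warn_tol=np.inf)
        B = eye + H0 @ Nt
        if np.linalg.cond(B) > 1e14:
            raise ConditioningError("forward potential blows up inside the horizon")
        H[i] = symmetrize(Phii.T @ np.linalg.solve(B, H0) @ Phii, warn_tol=np.inf)
        PH = Pi[i] + H[i]
        wPH = np.linalg.eigvalsh(PH)
        if wPH[0] <= 1e-14 * max(abs(wPH[-1]), 1e-300):
            raise ConditioningError("Pi(t) + H(t) is not positive definite on the grid")
        Sigma[i] = symmetrize(np.linalg.inv(PH), warn_tol=np.inf)
    return Pi, H, Sigma, Phi_t, M_0t, PhiT_t


def _boundary_residuals(problem: BridgeProblem, Pi0, H0, PiK, HK) -> tuple[float, float]:
    S0i = np.linalg.inv(problem.initial.sigma)
    STi = np.linalg.inv(problem.target.sigma)
    r0 = np.linalg.norm(Pi0 + H0 - S0i) / np.linalg.norm(S0i)
    rT = np.linalg.norm(PiK + HK - STi) / np.linalg.norm(STi)
    return float(r0), float(rT)


def _newton_polish(problem: BridgeProblem, PiT: np.ndarray) -> np.ndarray:
    """Damped Newton (via scipy root) on the terminal boundary residual."""
    n = problem.system.n
    iu = np.triu_indices(n)
    STi = np.linalg.inv(problem.target.sigma)

    def unpack(v):
        X = np.zeros((n, n))
        X[iu] = v
        return X + np.triu(X, 1).T

    def resid(v):
        X = unpack(v)
        try:
            Pi, H, *_ = _propagate_potentials(problem, X)
        except (ConditioningError, np.linalg.LinAlgError):
            return np.full(iu[0].size, 1e6)
        R = Pi[-1] + H[-1] - STi
        return R[iu]

    sol = root(resid, PiT[iu], method="hybr", tol=1e-12)
    if not sol.success:
        raise ConvergenceError(
            f"boundary solve did not converge; final residual {np.abs(sol.fun).max():.3e}"
        )
    return unpack(sol.x)


def solve_covariance_bridge(problem: BridgeProblem) -> BridgeSolution:
    """Solve the covariance part of the bridge: Pi(t), H(t), Sigma(t).

    The returned solution has the mean path filled in as well (it is cheap),
    so this is the full bridge solve; costs are attached by
    :func:`covariance_cost` / :func:`total_cost`.
    """
    system = problem.system
    T = problem.horizon
    S0, ST = problem.initial.sigma, problem.target.sigma
    Phi, M = transition_and_gramian(system, T)

    # zero-cost fixed point: target covariance equals the uncontrolled endpoint
    S_unc = symmetrize(Phi @ S0 @ Phi.T + M, warn_tol=np.inf)
    if np.linalg.norm(ST - S_unc) < 1e-10 * np.linalg.norm(S_unc):
        PiT = np.zeros((system.n, system.n))
    else:
        PiT = _terminal_potential(system, S0, ST, Phi, M)

    Pi, H, Sigma, Phi_t, M_0t, PhiT_t = _propagate_potentials(problem, PiT)
    r0, rT = _boundary_residuals(problem, Pi[0], H[0], Pi[-1], H[-1])
    if max(r0, rT) > 1e-8:
        PiT = _newton_polish(problem, PiT)
        Pi, H, Sigma, Phi_t, M_0t, PhiT_t = _propagate_potentials(problem, PiT)
        r0, rT = _boundary_residuals(problem, Pi[0], H[0], Pi[-1], H[-1])
        if max(r0, rT) > 1e-8:
            raise ConvergenceError(
                f"Schrödinger-system boundary residuals {r0:.3e}, {rT:.3e} exceed 1e-8"
            )

    mu_t, m_t = _mean_path(problem, Pi, Phi_t, M_0t, PhiT_t)
    J_mean = mean_cost(system, problem.initial.mu, problem.target.mu, T)
    sol = BridgeSolution(
        grid=problem.grid, Pi=Pi, H=H, Sigma_t=Sigma, mu_t=mu_t, m_t=m_t,
        J_mean=J_mean, J_cov=0.0, Phi_t=Phi_t, M_0t=M_0t, PhiT_t=PhiT_t,
    )
    sol.J_cov = covariance_cost(sol, problem)
    return sol


solve_bridge = solve_covariance_bridge


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

def mean_cost(system: LinearSystem, mu0: np.ndarray, muT: np.ndarray, T: float) -> float:
    """Mean control cost (mu_T - Phi(T) mu_0)^T M(T)^-1 (mu_T - Phi(T) mu_0).

    Equals the deterministic minimum-energy control cost with input matrix
    B = C; independent of the marginal covariances.
    """
    if not np.isfinite(T) or T <= 0:
        raise InvalidArgumentError("T must be finite and > 0")
    mu0 = np.atleast_1d(np.asarray(mu0, dtype=float))
    muT = np.atleast_1d(np.asarray(muT, dtype=float))
    if mu0.size != system.n or muT.size != system.n:
        raise InvalidArgumentError("mean vectors must have length n")
    Phi, M = transition_and_gramian(system, T)
    if np.linalg.cond(M) > 1e12:
        warnings.warn("Gramian M(T) is ill conditioned (cond > 1e12)", ConditioningWarning)
    mud = muT - Phi @ mu0
    return float(max(mud @ np.linalg.solve(M, mud), 0.0))


def covariance_cost(solution: BridgeSolution, problem: BridgeProblem) -> float:
    """Covariance control cost, boundary-term form, cross-checked against
    the integral form int tr(Pi S_C Pi Sigma) dt."""
    ts = solution.grid
    SC = problem.system.S_C
    tr_sc_pi = np.einsum("ij,tji->t", SC, solution.Pi)
    J1 = float(
        simpson(tr_sc_pi, x=ts)
        - (np.trace(solution.Pi[-1] @ problem.target.sigma)
           - np.trace(solution.Pi[0] @ problem.initial.sigma))
    )
    integrand = np.einsum("tij,jk,tkl,tli->t", solution.Pi, SC, solution.Pi, solution.Sigma_t)
    J2 = float(simpson(integrand, x=ts))
    scale = max(abs(J1), abs(J2), 1e-12)
    if abs(J1 - J2) / scale > 1e-4:
        raise ConsistencyError(
            f"covariance-cost identity mismatch: {J1:.6e} vs {J2:.6e}"
        )
    return max(J1, 0.0)


def total_cost(problem: BridgeProblem, refine: bool = True,
               rtol: float = 1e-6, max_refinements: int = 3) -> tuple[float, float, float]:
    """(J_mean, J_cov, J_total) for the bridge, with adaptive grid refinement.

    The grid is doubled until J_cov changes by less than ``rtol`` relative.
    """
    sol = solve_covariance_bridge(problem)
    if refine:
        k = problem.grid.size - 1
        prev = sol.J_cov
        for _ in range(max_refinements):
            k *= 2
            sol2 = solve_covariance_bridge(problem.with_grid(k))
            if abs(sol2.J_cov - prev) <= rtol * max(abs(prev), 1e-12):
                sol = sol2
                break
            prev, sol = sol2.J_cov, sol2
    return sol.J_mean, sol.J_cov, sol.J_mean + sol.J_cov


# ---------------------------------------------------------------------------
# mean path, feedforward, node inputs
# ---------------------------------------------------------------------------

def _mean_path(problem: BridgeProblem, Pi, Phi_t, M_0t, PhiT_t):
    mu0, muT = problem.initial.mu, problem.target.mu
    M = M_0t[-1]
    mud = muT - Phi_t[-1] @ mu0
    w = np.linalg.solve(M, mud)
    f = np.einsum("tji,j->ti", PhiT_t, w)              # Phi(T,t)^T M^-1 mu_d
    mu_t = np.einsum("tij,j->ti", Phi_t, mu0) + np.einsum("tij,tj->ti", M_0t, f)
    m_t = np.einsum("tij,tj->ti", Pi, mu_t) + f
    return mu_t, m_t


def mean_path_and_feedforward(problem: BridgeProblem, Pi: np.ndarray):
    """Optimal mean trajectory mu(t) and feedforward offset m(t) on the grid.

    mu(t) = Phi(t,0) mu_0 + M(0,t) Phi(T,t)^T M(T)^-1 (mu_T - Phi(T,0) mu_0),
    m(t)  = Pi(t) mu(t) + Phi(T,t)^T M(T)^-1 (mu_T - Phi(T,0) mu_0),

    so the closed loop d mu/dt = A mu - S_C (Pi mu - m) steers mu_0 to mu_T.
    """
    system = problem.system
    ts = problem.grid
    n = system.n
    K1 = ts.size
    Phi_t = np.empty((K1, n, n))
    M_0t = np.empty((K1, n, n))
    PhiT_t = np.empty((K1, n, n))
    for i, t in enumerate(ts):
        Phi_t[i], M_0t[i] = transition_and_gramian(system, t)
        PhiT_t[i] = expm(system.A * (problem.horizon - t))
    return _mean_path(problem, Pi, Phi_t, M_0t, PhiT_t)


def node_inputs(problem: BridgeProblem, solution: BridgeSolution,
                roi_names: list[str] | None = None) -> InputMap:
    """Per-node expected squared control input, split into mean/covariance parts.

    I_mean(k) = (S_C int (Pi mu - m)(Pi mu - m)^T dt S_C)_kk,
    I_cov(k)  = (S_C int Pi Sigma Pi dt S_C)_kk.

    With S_C = I the node inputs sum exactly to J_total.
    """
    ts = solution.grid
    SC = problem.system.S_C
    g = np.einsum("tij,tj->ti", solution.Pi, solution.mu_t) - solution.m_t
    Gm = simpson(np.einsum("ti,tj->tij", g, g), x=ts, axis=0)
    Gc = simpson(
        np.einsum("tij,tjk,tkl->til", solution.Pi, solution.Sigma_t, solution.Pi),
        x=ts, axis=0,
    )
    I_mean = np.einsum("ij,jk,ki->i", SC, Gm, SC)
    I_cov = np.einsum("ij,jk,ki->i", SC, Gc, SC)
    if roi_names is None:
        roi_names = [f"roi_{k:03d}" for k in range(problem.system.n)]
    return InputMap(tuple(roi_names), np.clip(I_mean, 0.0, None), np.clip(I_cov, 0.0, None))
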