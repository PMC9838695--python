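"""Shared generators and independent oracles used across the test suite.

The oracles here deliberately avoid the code paths they are used to check:
the scalar bridge boundary oracle solves the one-dimensional boundary
system by bracketed root finding on the linear flow representations; the
discretized minimum-energy oracle computes the deterministic control cost
by a Riemann-sum Gramian over piecewise-constant controls.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from ctrlbridge import (
    BridgeProblem,
    CohortSpec,
    GaussianState,
    LinearSystem,
    make_random_stable_system,
)
from ctrlbridge.synthetic import random_spd


def rand_state(n: int, rng: np.random.Generator, mean_scale: float = 1.0,
               cov_scale: float = 1.0) -> GaussianState:
    return GaussianState(
        mean_scale * rng.normal(size=n),
        random_spd(n, rng, max_cond=30.0, scale=cov_scale),
    )


def random_bridge_problem(n: int, seed: int, T: float = 1.0,
                          zero_means: bool = False) -> BridgeProblem:
    rng = np.random.default_rng(seed)
    system = make_random_stable_system(n, sparsity=0.3 if n > 2 else 0.0, seed=seed + 10_000)
    ini = rand_state(n, rng, mean_scale=0.0 if zero_means else 1.0)
    tgt = rand_state(n, rng, mean_scale=0.0 if zero_means else 1.0)
    return BridgeProblem(system, ini, tgt, T)


def scalar_pi0_oracle(system: LinearSystem, s0: float, sT: float, T: float) -> float:
    """Pi(0) of the 1-D bridge by root finding on the boundary system.

    Uses the linear flows Q(t) = Phi^2 Q(0) - M(t) and P(t) = Phi^2 P(0) + M(t)
    of Q = 1/Pi and P = 1/H, eliminating H(0) = 1/s0 - Pi(0).
    """
    a = float(system.A[0, 0])
    c2 = float(system.S_C[0, 0])
    phi2 = np.exp(2 * a * T)
    M = c2 * (np.expm1(2 * a * T)) / (2 * a) if a != 0 else c2 * T

    def resid(x: float) -> float:
        # terminal precision 1/sT = Pi(T) + H(T) as a function of x = Pi(0);
        # Q(T) = phi2 / x - M with Q(0) = 1/x (x = 0 excluded by the bracket scan)
        qT = phi2 / x - M
        h0 = 1.0 / s0 - x
        pT = phi2 / h0 + M
        return 1.0 / qT + 1.0 / pT - 1.0 / sT

    # bracket: Pi(0) lies in (-inf, 1/s0); scan for a sign change
    xs = np.concatenate([
        -np.geomspace(1e3, 1e-8, 300), np.geomspace(1e-8, 0.999999 / s0, 300),
    ])
    vals = []
    for x in xs:
        try:
            vals.append(resid(x))
        except ZeroDivisionError:
            vals.append(np.nan)
    vals = np.asarray(vals)
    for i in range(len(xs) - 1):
        if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) and vals[i] * vals[i + 1] < 0:
            return brentq(resid, xs[i], xs[i + 1], xtol=1e-14)
    raise RuntimeError("no sign change found for the scalar boundary system")


def min_energy_cost_discrete(system: LinearSystem, mu0: np.ndarray, muT: np.ndarray,
                             T: float, dt: float = 1e-3) -> float:
    """Deterministic minimum-energy cost by discretized open-loop control.

    Steers the noiseless mean ODE  x' = A x + v  with piecewise-constant v
    on steps of size dt; the least weighted-norm control solving the
    discrete reachability system gives cost  d^T M_d^-1 d  with the
    Riemann-sum Gramian  M_d = dt * sum_j Phi_dt^j S_C (Phi_dt^j)^T.
    """
    n = system.n
    N = int(round(T / dt))
    Phid = expm(system.A * (T / N))
    Md = np.zeros((n, n))
    P = np.eye(n)
    for _ in range(N):
        Md += P @ system.S_C @ P.T * (T / N)
        P = Phid @ P
    d = np.asarray(muT) - P @ np.asarray(mu0)
    return float(d @ np.linalg.solve(Md, d))


# ---------------------------------------------------------------------------
# study-condition cohorts
# ---------------------------------------------------------------------------

def study_system(n: int, seed: int = 7) -> LinearSystem:
    """Ground-truth resting dynamics for cohort studies.

    Random sparse stable drift whose spectrum is mapped affinely into
    Re(lambda) in [-1.3, -0.3] per time unit: modes much faster than the
    sampling interval are unidentifiable, modes much slower never
    decorrelate within a task block, and neither is seen in parcellated
    BOLD.  The noise rate is rescaled so the stationary covariance has
    trace n (unit per-ROI variance on average), emulating
    variance-normalized signals.
    """
    from ctrlbridge import steady_state

    raw = make_random_stable_system(n, sparsity=0.5, seed=seed)
    lam = np.linalg.eigvals(raw.A).real
    alpha = min(1.0, 1.0 / (lam.max() - lam.min())) if n > 1 else 1.0
    A = alpha * raw.A - (alpha * lam.max() + 0.3) * np.eye(n)
    slowed = LinearSystem(A, raw.S_C)
    tr = np.trace(steady_state(slowed).sigma)
    return LinearSystem(slowed.A, slowed.S_C * (n / tr))


N_ROIS = 6
N_SUBJECTS = 20
REST_LENGTH = 600
TASK_LENGTH = 600
BLOCK_LENGTH = 30
DT = 0.72


def mean_effect_delta(n: int = N_ROIS) -> np.ndarray:
    """Focal mean shift: a single ROI activates by half a standard deviation."""
    delta = np.zeros(n)
    delta[1] = 0.5
    return delta


def cov_effect_modulator(n: int = N_ROIS, seed: int = 5) -> np.ndarray:
    """Spread covariance reshaping: a full random rotation plus mild per-ROI
    variance scaling, so the functional-connectivity change touches every ROI."""
    rng = np.random.default_rng(seed)
    scales = 1.0 + 0.25 * np.cos(np.arange(n) * 2.4)   # in [0.75, 1.25]
    Q = np.linalg.qr(rng.normal(size=(n, n)))[0]
    return Q @ np.diag(scales)


def study_cohort_spec(kind: str, n: int = N_ROIS, seed: int = 3) -> CohortSpec:
    """Cohort with a mean-only ('mean'), covariance-only ('cov'), or null task effect."""
    if kind == "mean":
        delta, L = mean_effect_delta(n), np.eye(n)
    elif kind == "cov":
        delta, L = np.zeros(n), cov_effect_modulator(n)
    elif kind == "null":
        delta, L = np.zeros(n), np.eye(n)
    else:
        raise ValueError(kind)
    return CohortSpec(
        n_subjects=N_SUBJECTS,
        n_rois=n,
        rest_length=REST_LENGTH,
        task_length=TASK_LENGTH,
        dt=DT,
        block_length=BLOCK_LENGTH,
        mean_offsets={f"{kind}task": delta},
        cov_modulators={f"{kind}task": L},
        subject_scales=np.linspace(0.5, 2.0, N_SUBJECTS),
        seed=seed,
    )
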