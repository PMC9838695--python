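"""Synthetic ground-truth systems, OU trajectories, controlled-path Monte Carlo,
and multi-subject rest/task cohorts.

Every generator is fully seeded, so tests and the acceptance script are
reproducible without any external data.  The controlled-path simulator is
the independent oracle for the bridge solver: it integrates the optimally
controlled SDE by Euler-Maruyama and records the realized quadratic cost
per path and per node, which must agree with the analytical values within
Monte-Carlo error.

Cohorts emulate multi-subject resting and task runs: the resting run is
steady-state OU; task runs alternate task-free blocks (steady-state OU)
with task-performing blocks whose samples are affinely transformed to have
mean shifted by delta and covariance L Sigma_0 L^T.  Ground truth for the
estimation pipeline is therefore exact by construction.  Per-subject scale
factors mimic the arbitrary units of BOLD signals, which downstream trace
normalization must remove.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.linalg import cholesky

from .bridge import BridgeProblem, BridgeSolution
from .estimation import REST, TASK_FREE, TASK_PERFORMING, TimeSeriesData
from .exceptions import InvalidArgumentError, ResolutionError
from .linsde import (
    GaussianState,
    LinearSystem,
    exact_discretization,
    steady_state,
)

__all__ = [
    "CohortSpec",
    "SubjectData",
    "PathStatistics",
    "make_random_stable_system",
    "random_spd",
    "simulate_ou_series",
    "simulate_controlled_paths",
    "generate_cohort",
]


def random_spd(n: int, rng: np.random.Generator, max_cond: float = 100.0,
               scale: float = 1.0) -> np.ndarray:
    """Random symmetric positive-definite matrix with bounded condition number."""
    Q = np.linalg.qr(rng.normal(size=(n, n)))[0]
    w = np.exp(rng.uniform(0.0, np.log(max_cond), size=n))
    w = w / np.exp(0.5 * np.log(w).mean()) * scale   # geometric mean -> scale
    return (Q * w) @ Q.T


def make_random_stable_system(n: int, sparsity: float = 0.0, seed: int = 0) -> LinearSystem:
    """Random stable OU system: max Re(eigenvalue of A) <= -0.1, S_C PD (cond <= 100).

    ``sparsity`` is the fraction of off-diagonal entries of A forced to zero.
    """
    if not 0 <= sparsity < 1:
        raise InvalidArgumentError("sparsity must be in [0, 1)")
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, n))
    if n > 1 and sparsity > 0:
        off = [(i, j) for i in range(n) for j in range(n) if i != j]
        n_zero = int(round(sparsity * len(off)))
        for idx in rng.choice(len(off), size=n_zero, replace=False):
            A[off[idx]] = 0.0
    # shift the diagonal to enforce the stability margin (preserves sparsity)
    shift = max(np.linalg.eigvals(A).real.max(), 0.0) + 0.1 + rng.uniform(0.1, 0.5)
    A = A - shift * np.eye(n)
    S_C = random_spd(n, rng)
    return LinearSystem(A, S_C)


def simulate_ou_series(
    system: LinearSystem,
    x0_state: GaussianState,
    dt: float,
    n_steps: int,
    seed: int = 0,
    labels: np.ndarray | None = None,
    subject_id: str = "",
) -> TimeSeriesData:
    """Exact-in-law OU sampling at the grid via the one-step exact discretization.

    Returns ``n_steps`` rows; the first row is the draw from ``x0_state``.
    """
    if n_steps < 1:
        raise InvalidArgumentError("n_steps must be >= 1")
    a, Sd = exact_discretization(system, dt)
    rng = np.random.default_rng(seed)
    n = system.n
    x = np.empty((n_steps, n))
    if np.linalg.eigvalsh(x0_state.sigma)[-1] > 0:
        L0 = cholesky(x0_state.sigma + 1e-15 * np.eye(n), lower=True)
        x[0] = x0_state.mu + L0 @ rng.standard_normal(n)
    else:
        x[0] = x0_state.mu
    wS = np.linalg.eigvalsh(Sd)
    Ld = cholesky(Sd + max(wS[-1], 1.0) * 1e-14 * np.eye(n), lower=True)
    eps = rng.standard_normal((n_steps - 1, n)) @ Ld.T
    for t in range(n_steps - 1):
        x[t + 1] = a @ x[t] + eps[t]
    return TimeSeriesData(x, dt, labels=labels, subject_id=subject_id)


# ---------------------------------------------------------------------------
# controlled-path Monte Carlo (the oracle for the bridge solver)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathStatistics:
    """Endpoint samples and realized quadratic costs of simulated controlled paths."""

    endpoints: np.ndarray        # (n_paths, n)
    path_cost: np.ndarray        # (n_paths,)  int ||v||^2_{S_C^-1} dt
    node_cost: np.ndarray        # (n_paths, n)  int v_k^2 dt

    @property
    def n_paths(self) -> int:
        return self.endpoints.shape[0]

    def cost_mean_se(self) -> tuple[float, float]:
        return float(self.path_cost.mean()), float(self.path_cost.std(ddof=1) / np.sqrt(self.n_paths))

    def node_mean_se(self) -> tuple[np.ndarray, np.ndarray]:
        return self.node_cost.mean(axis=0), self.node_cost.std(axis=0, ddof=1) / np.sqrt(self.n_paths)

    def endpoint_mean_se(self) -> tuple[np.ndarray, np.ndarray]:
        return self.endpoints.mean(axis=0), self.endpoints.std(axis=0, ddof=1) / np.sqrt(self.n_paths)


def simulate_controlled_paths(
    problem: BridgeProblem,
    solution: BridgeSolution,
    n_paths: int = 20_000,
    euler_dt: float | None = None,
    seed: int = 0,
) -> PathStatistics:
    """Euler-Maruyama simulation of dx = A x dt + v* dt + C dw with the optimal
    feedback v* = -S_C (Pi(t) x - m(t)); Pi and m are linearly interpolated
    between grid points.

    Records, per path, the endpoint x(T), the realized weighted quadratic
    cost int ||v||^2_{S_C^-1} dt and the per-node costs int v_k^2 dt.
    """
    T = problem.horizon
    if euler_dt is None:
        euler_dt = T / 1000.0
    if euler_dt > T / 500.0 + 1e-15:
        raise ResolutionError("euler_dt must be at most T/500 for oracle accuracy")
    system = problem.system
    n = system.n
    SC = system.S_C
    SCi = np.linalg.inv(SC)
    C = cholesky(SC, lower=True)
    rng = np.random.default_rng(seed)

    n_steps = int(round(T / euler_dt))
    dt = T / n_steps
    ts = solution.grid

    L0 = cholesky(problem.initial.sigma, lower=True)
    x = problem.initial.mu + rng.standard_normal((n_paths, n)) @ L0.T
    cost = np.zeros(n_paths)
    node = np.zeros((n_paths, n))
    sqdt = np.sqrt(dt)
    for kstep in range(n_steps):
        t = kstep * dt
        j = min(np.searchsorted(ts, t, side="right") - 1, ts.size - 2)
        w = (t - ts[j]) / (ts[j + 1] - ts[j])
        Pk = (1 - w) * solution.Pi[j] + w * solution.Pi[j + 1]
        mk = (1 - w) * solution.m_t[j] + w * solution.m_t[j + 1]
        v = -(x @ Pk.T - mk) @ SC.T
        cost += np.einsum("ij,jk,ik->i", v, SCi, v) * dt
        node += v * v * dt
        x = x + (x @ system.A.T + v) * dt + rng.standard_normal((n_paths, n)) @ C.T * sqdt
    return PathStatistics(x, cost, node)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a multi-subject rest/task cohort from a known OU system.

    ``mean_offsets[task]`` is the task-performing mean shift delta;
    ``cov_modulators[task]`` the mixing matrix L giving task covariance
    L Sigma_0 L^T.  ``subject_scales`` are positive per-subject factors
    multiplying the raw signals (removed downstream by trace normalization).
    """

    n_subjects: int
    n_rois: int
    rest_length: int
    task_length: int
    dt: float
    block_length: int
    mean_offsets: Mapping[str, np.ndarray]
    cov_modulators: Mapping[str, np.ndarray]
    subject_scales: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("n_subjects", self.n_subjects), ("n_rois", self.n_rois),
                        ("rest_length", self.rest_length), ("task_length", self.task_length),
                        ("block_length", self.block_length)):
            if int(v) < 1:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.block_length > self.task_length:
            raise InvalidArgumentError("block_length exceeds task_length")
        if set(self.mean_offsets) != set(self.cov_modulators):
            raise InvalidArgumentError("mean_offsets and cov_modulators must share task names")
        offs = {k: np.asarray(v, dtype=float) for k, v in self.mean_offsets.items()}
        mods = {k: np.asarray(v, dtype=float) for k, v in self.cov_modulators.items()}
        for k in offs:
            if offs[k].shape != (self.n_rois,) or mods[k].shape != (self.n_rois, self.n_rois):
                raise InvalidArgumentError(f"bad shapes for task {k!r}")
            if abs(np.linalg.det(mods[k])) < 1e-12:
                raise InvalidArgumentError(f"cov modulator for task {k!r} is singular")
        scales = self.subject_scales
        scales = np.ones(self.n_subjects) if scales is None else np.asarray(scales, dtype=float)
        if scales.shape != (self.n_subjects,) or (scales <= 0).any():
            raise InvalidArgumentError("subject_scales must be positive, one per subject")
        object.__setattr__(self, "mean_offsets", offs)
        object.__setattr__(self, "cov_modulators", mods)
        object.__setattr__(self, "subject_scales", scales)

    @property
    def tasks(self) -> tuple[str, ...]:
        return tuple(sorted(self.mean_offsets))

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects, "n_rois": self.n_rois,
            "rest_length": self.rest_length, "task_length": self.task_length,
            "dt": self.dt, "block_length": self.block_length,
            "mean_offsets": {k: v.tolist() for k, v in self.mean_offsets.items()},
            "cov_modulators": {k: v.tolist() for k, v in self.cov_modulators.items()},
            "subject_scales": self.subject_scales.tolist(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(
            n_subjects=int(d["n_subjects"]), n_rois=int(d["n_rois"]),
            rest_length=int(d["rest_length"]), task_length=int(d["task_length"]),
            dt=float(d["dt"]), block_length=int(d["block_length"]),
            mean_offsets={k: np.asarray(v) for k, v in d["mean_offsets"].items()},
            cov_modulators={k: np.asarray(v) for k, v in d["cov_modulators"].items()},
            subject_scales=np.asarray(d["subject_scales"]) if d.get("subject_scales") else None,
            seed=int(d.get("seed", 0)),
        )


@dataclass(frozen=True)
class SubjectData:
    """One subject's resting run plus one run per task."""

    subject_id: str
    rest: TimeSeriesData
    tasks: Mapping[str, TimeSeriesData]


def generate_cohort(spec: CohortSpec, system: LinearSystem) -> list[SubjectData]:
    """Generate rest and task runs for every subject in the cohort.

    Rest runs are steady-state OU.  Task runs alternate task-free blocks
    (raw steady-state OU) and task-performing blocks, whose samples x are
    replaced by delta + L x so their law is exactly N(delta, L Sigma_0 L^T).
    The whole subject is finally multiplied by its scale factor.
    """
    if system.n != spec.n_rois:
        raise InvalidArgumentError("system dimension does not match n_rois")
    ss = steady_state(system)   # raises StabilityError for unstable systems
    root = np.random.SeedSequence(spec.seed)
    subj_seeds = root.spawn(spec.n_subjects)
    out = []
    for s in range(spec.n_subjects):
        seeds = subj_seeds[s].generate_state(1 + len(spec.tasks)) % (2**31 - 1)
        scale = spec.subject_scales[s]
        sid = f"sub{s:03d}"
        rest = simulate_ou_series(
            system, ss, spec.dt, spec.rest_length, seed=int(seeds[0]),
            labels=np.full(spec.rest_length, REST), subject_id=sid,
        )
        rest = TimeSeriesData(rest.values * scale, spec.dt, rest.labels, sid)
        tasks = {}
        for j, task in enumerate(spec.tasks):
            raw = simulate_ou_series(system, ss, spec.dt, spec.task_length,
                                     seed=int(seeds[1 + j]))
            labels = np.full(spec.task_length, TASK_FREE, dtype=object)
            block = spec.block_length
            # alternate free/performing blocks, starting with a free block
            pos = block
            while pos < spec.task_length:
                end = min(pos + block, spec.task_length)
                labels[pos:end] = TASK_PERFORMING
                pos = end + block
            vals = raw.values.copy()
            mask = labels == TASK_PERFORMING
            delta = spec.mean_offsets[task]
            L = spec.cov_modulators[task]
            vals[mask] = delta + vals[mask] @ L.T
            tasks[task] = TimeSeriesData(
                vals * scale, spec.dt, np.asarray(labels, dtype=str), sid
            )
        out.append(SubjectData(sid, rest, tasks))
    return out
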