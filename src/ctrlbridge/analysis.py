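"""Config-driven transition-cost analysis on a cohort, plus reporting analytics.

``run_transition_analysis`` reproduces the full bootstrap procedure on any
cohort: in each replicate it draws k subjects, estimates the resting
dynamics (A, S_C) from their pooled, trace-normalized resting runs by
sparse VAR(1) + continuous-time conversion, estimates the rest and task
Gaussian states, solves the Schrödinger bridge from rest to each task, and
records the cost decomposition and per-ROI input maps.

The smaller functions are the map analytics: entropy of an input map,
top-k membership counts across tasks, the smallest ROI subset covering a
fraction of the total input, and the correlation of a map with activation
|t| values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bridge import BridgeProblem, node_inputs, solve_covariance_bridge
from .estimation import (
    TASK_FREE,
    concatenate_series,
    estimate_rest_state,
    estimate_task_state,
    fit_var_lasso,
    match_rest_covariance,
    select_lambda_cv,
    shrink_to_diagonal,
    task_activation_tvalues,
    to_continuous_system,
    trace_normalize,
)
from .exceptions import InvalidArgumentError, SchemaError
from .linsde import GaussianState
from .reports import CostReport, InputMap
from .synthetic import SubjectData

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "run_transition_analysis",
    "input_map_entropy",
    "top_k_membership_counts",
    "coverage_selection",
    "activation_correlation",
]

logger = logging.getLogger("ctrlbridge")


@dataclass(frozen=True)
class RunConfig:
    """Tunable knobs of the transition analysis.

    horizon T in the time units of dt; ``lambda_mode`` is "cv" (5-fold
    cross-validated lasso penalty) or "fixed" (use ``lambda_value``, 0 = OLS).
    """

    T: float = 1.0
    dt: float = 0.72
    lambda_mode: str = "cv"
    lambda_value: float = 0.0
    bootstrap_k: int = 100
    bootstrap_reps: int = 100
    seed: int = 0
    grid_points: int = 200
    max_cond: float = 1e8
    # replace the fitted S_C so the implied steady state equals the empirical
    # rest covariance exactly (off: keep the residual-implied noise rate)
    match_rest_cov: bool = False

    def __post_init__(self) -> None:
        if self.lambda_mode not in ("cv", "fixed"):
            raise InvalidArgumentError("lambda_mode must be 'cv' or 'fixed'")
        if self.T <= 0 or self.dt <= 0:
            raise InvalidArgumentError("T and dt must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        lam = d.get("lambda", {})
        bs = d.get("bootstrap", {})
        return cls(
            T=float(d.get("T", 1.0)),
            dt=float(d.get("dt", 0.72)),
            lambda_mode=str(lam.get("mode", "cv")),
            lambda_value=float(lam.get("value", 0.0)),
            bootstrap_k=int(bs.get("k", 100)),
            bootstrap_reps=int(bs.get("reps", 100)),
            seed=int(bs.get("seed", 0)),
            grid_points=int(d.get("grid_points", 200)),
            match_rest_cov=bool(d.get("match_rest_cov", False)),
        )


@dataclass
class AnalysisResult:
    """Costs and maps of every successful bootstrap replicate."""

    report: CostReport
    input_maps: dict[str, list[InputMap]]          # task -> per-replicate maps
    tvalues: dict[str, list[np.ndarray]]           # task -> per-replicate |t| inputs
    failures: list[tuple[int, str]] = field(default_factory=list)

    def mean_map(self, task: str) -> InputMap:
        maps = self.input_maps[task]
        return InputMap(
            maps[0].roi_names,
            np.mean([m.I_mean for m in maps], axis=0),
            np.mean([m.I_cov for m in maps], axis=0),
        )

    def cross_task_average_map(self) -> InputMap:
        """Average of per-task mean maps, each normalized by its summed total input."""
        normed = [self.mean_map(t).normalized() for t in sorted(self.input_maps)]
        return InputMap(
            normed[0].roi_names,
            np.mean([m.I_mean for m in normed], axis=0),
            np.mean([m.I_cov for m in normed], axis=0),
        )


def _replicate(cohort: Sequence[SubjectData], idx: np.ndarray, config: RunConfig,
               rep: int, report: CostReport, maps, tvals) -> None:
    rest_parts = [trace_normalize(cohort[i].rest, None) for i in idx]
    rest_concat = concatenate_series(rest_parts)
    if config.lambda_mode == "cv":
        lam = select_lambda_cv(rest_concat, seed=config.seed + rep)
    else:
        lam = config.lambda_value
    fit = fit_var_lasso(rest_concat, lam)
    system = to_continuous_system(fit, config.dt)
    rest_state = estimate_rest_state(rest_concat)
    rest_state = GaussianState(rest_state.mu, shrink_to_diagonal(rest_state.sigma, config.max_cond))
    if config.match_rest_cov:
        system = match_rest_covariance(system, rest_state.sigma)
    tasks = sorted(cohort[0].tasks)
    for task in tasks:
        task_parts = [trace_normalize(cohort[i].tasks[task], TASK_FREE) for i in idx]
        task_concat = concatenate_series(task_parts)
        st = estimate_task_state(task_concat)
        st = GaussianState(st.mu, shrink_to_diagonal(st.sigma, config.max_cond))
        problem = BridgeProblem(
            system, rest_state, st, config.T,
            np.linspace(0.0, config.T, config.grid_points + 1),
        )
        sol = solve_covariance_bridge(problem)
        report.add(task, rep, sol.J_mean, sol.J_cov)
        roi = cohort[0].rest.roi_names or [f"roi_{k:03d}" for k in range(system.n)]
        maps.setdefault(task, []).append(node_inputs(problem, sol, list(roi)))
        tvals.setdefault(task, []).append(np.abs(task_activation_tvalues(task_concat)))
        logger.info(
            "rep %d task %s: J_mean=%.4g J_cov=%.4g lambda=%.3g", rep, task,
            sol.J_mean, sol.J_cov, lam,
        )


def run_transition_analysis(cohort: Sequence[SubjectData], config: RunConfig) -> AnalysisResult:
    """Bootstrap transition-cost analysis over a cohort of subjects.

    Deterministic given ``config.seed``.  Replicates that fail (singular
    estimates, non-convergent bridge) are recorded; more than 10% failures
    aborts the run.
    """
    if not cohort:
        raise InvalidArgumentError("empty cohort")
    if config.bootstrap_k > len(cohort):
        raise InvalidArgumentError("bootstrap k exceeds the number of subjects")
    rng = np.random.default_rng(config.seed)
    report = CostReport()
    maps: dict[str, list[InputMap]] = {}
    tvals: dict[str, list[np.ndarray]] = {}
    failures: list[tuple[int, str]] = []
    for rep in range(config.bootstrap_reps):
        idx = np.sort(rng.choice(len(cohort), size=config.bootstrap_k, replace=False))
        try:
            _replicate(cohort, idx, config, rep, report, maps, tvals)
        except Exception as exc:  # noqa: BLE001 - replicate-level fault isolation
            failures.append((rep, f"{type(exc).__name__}: {exc}"))
            logger.warning("replicate %d failed: %s", rep, exc)
        if len(failures) > 0.1 * config.bootstrap_reps:
            raise RuntimeError(
                f"more than 10% of replicates failed; first failure: {failures[0][1]}"
            )
    return AnalysisResult(report, maps, tvals, failures)


# ---------------------------------------------------------------------------
# map analytics
# ---------------------------------------------------------------------------

def input_map_entropy(map_vector: np.ndarray) -> float:
    """Shannon entropy (natural log) of a nonnegative input map.

    Zero entries contribute nothing; the maximum log(n) is attained by the
    uniform map.
    """
    v = np.asarray(map_vector, dtype=float)
    if v.ndim != 1 or (v < 0).any():
        raise InvalidArgumentError("input map must be a nonnegative vector")
    s = v.sum()
    if s <= 0:
        raise InvalidArgumentError("input map is all zero")
    p = v[v > 0] / s
    p = p[p > 0]  # guard subnormal entries that underflow to 0 when normalized
    return float(-(p * np.log(p)).sum())


def _rank_order(v: np.ndarray) -> np.ndarray:
    """Indices sorted by descending value; ties broken by ascending ROI index."""
    return np.argsort(-v, kind="stable")


def top_k_membership_counts(maps: Sequence[InputMap], k: int) -> dict[str, np.ndarray]:
    """Count, per ROI, in how many tasks it ranks in the top k.

    Returns counts for each of "I_mean", "I_cov", "I_total".
    """
    if not maps:
        raise InvalidArgumentError("no maps given")
    names = maps[0].roi_names
    if any(m.roi_names != names for m in maps):
        raise SchemaError("all maps must share the same ROI names")
    if not 1 <= k <= len(names):
        raise InvalidArgumentError("k must be between 1 and the number of ROIs")
    out = {}
    for comp in ("I_mean", "I_cov", "I_total"):
        counts = np.zeros(len(names), dtype=int)
        for m in maps:
            counts[_rank_order(getattr(m, comp))[:k]] += 1
        out[comp] = counts
    return out


def coverage_selection(map_vector: np.ndarray, fraction: float) -> np.ndarray:
    """Smallest prefix of ROIs (sorted by descending input) whose cumulative
    share of the summed input reaches ``fraction``.  Returns ROI indices in
    selection order."""
    if not 0 < fraction <= 1:
        raise InvalidArgumentError("fraction must be in (0, 1]")
    v = np.asarray(map_vector, dtype=float)
    s = v.sum()
    if s <= 0:
        raise InvalidArgumentError("input map is all zero")
    order = _rank_order(v)
    if fraction == 1.0:
        return order[v[order] > 0]
    cum = np.cumsum(v[order]) / s
    stop = int(np.searchsorted(cum, fraction - 1e-12)) + 1
    return order[:stop]


def activation_correlation(input_map: np.ndarray, activation_t: np.ndarray) -> float:
    """Pearson correlation between an input map and absolute activation t values."""
    x = np.asarray(input_map, dtype=float)
    y = np.abs(np.asarray(activation_t, dtype=float))
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InvalidArgumentError("vectors must share a length of at least 3")
    if x.std() == 0 or y.std() == 0:
        raise InvalidArgumentError("correlation undefined: zero variance input")
    return float(np.corrcoef(x, y)[0, 1])
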