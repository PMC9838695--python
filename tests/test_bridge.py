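"""Bridge solver: boundary contracts, cost decomposition, oracles."""

import numpy as np
import pytest
from scipy.integrate import simpson, solve_ivp

import ctrlbridge as cb
from ctrlbridge.exceptions import InvalidArgumentError

from helpers import (
    min_energy_cost_discrete,
    rand_state,
    random_bridge_problem,
    scalar_pi0_oracle,
)


def frob_rel(X, Y):
    return np.linalg.norm(X - Y) / max(np.linalg.norm(Y), 1e-300)


@pytest.fixture(scope="module")
def generic_problem():
    return random_bridge_problem(3, seed=17)


@pytest.fixture(scope="module")
def generic_solution(generic_problem):
    return cb.solve_bridge(generic_problem)


class TestCovarianceBridge:
    def test_zero_control_fixed_point(self):
        """Target = uncontrolled endpoint: Pi vanishes, H is the inverse of the
        uncontrolled covariance along the whole path, J_cov = 0."""
        sys_ = cb.make_random_stable_system(3, seed=1)
        ini = cb.GaussianState(np.zeros(3), cb.steady_state(sys_).sigma)
        tgt = cb.propagate_uncontrolled(sys_, ini, 1.0)
        prob = cb.BridgeProblem(sys_, ini, tgt, 1.0)
        sol = cb.solve_bridge(prob)
        assert np.abs(sol.Pi).max() < 1e-10
        assert sol.J_cov < 1e-8 * 3
        for i in (0, len(sol.grid) // 2, -1):
            unc = cb.propagate_uncontrolled(sys_, ini, float(sol.grid[i]))
            assert frob_rel(sol.H[i], np.linalg.inv(unc.sigma)) < 1e-8

    def test_scalar_boundary_oracle(self):
        """Pi(0), H(0) match an independent scalar root-finder on the boundary system."""
        sys_ = cb.LinearSystem([[-0.9]], [[1.4]])
        s0, sT, T = 0.6, 1.9, 1.0
        prob = cb.BridgeProblem(
            sys_, cb.GaussianState([0.0], [[s0]]), cb.GaussianState([0.0], [[sT]]), T
        )
        sol = cb.solve_bridge(prob)
        pi0 = scalar_pi0_oracle(sys_, s0, sT, T)
        assert sol.Pi[0][0, 0] == pytest.approx(pi0, abs=1e-8)
        assert sol.H[0][0, 0] == pytest.approx(1.0 / s0 - pi0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_boundary_residuals_random(self, seed):
        n = 1 + seed % 8
        prob = random_bridge_problem(n, seed=100 + seed)
        sol = cb.solve_bridge(prob)
        S0i = np.linalg.inv(prob.initial.sigma)
        STi = np.linalg.inv(prob.target.sigma)
        assert frob_rel(sol.Pi[0] + sol.H[0], S0i) < 1e-8
        assert frob_rel(sol.Pi[-1] + sol.H[-1], STi) < 1e-8
        # Pi + H (the covariance inverse) must be PD on the whole grid
        for i in range(0, len(sol.grid), 20):
            assert np.linalg.eigvalsh(sol.Pi[i] + sol.H[i]).min() > 0

    def test_marginals_reproduced(self, generic_problem, generic_solution):
        sol, prob = generic_solution, generic_problem
        assert frob_rel(sol.Sigma_t[0], prob.initial.sigma) < 1e-6
        assert frob_rel(sol.Sigma_t[-1], prob.target.sigma) < 1e-6
        assert np.linalg.norm(sol.mu_t[0] - prob.initial.mu) < 1e-8
        assert np.linalg.norm(sol.mu_t[-1] - prob.target.mu) < 1e-8

    def test_riccati_satisfied_midgrid(self, generic_problem, generic_solution):
        """Finite-difference check of dPi/dt = -A^T Pi - Pi A + Pi S_C Pi."""
        sol, prob = generic_solution, generic_problem
        A, SC = prob.system.A, prob.system.S_C
        i = len(sol.grid) // 2
        dt = sol.grid[1] - sol.grid[0]
        Pidot = (sol.Pi[i + 1] - sol.Pi[i - 1]) / (2 * dt)
        rhs = -A.T @ sol.Pi[i] - sol.Pi[i] @ A + sol.Pi[i] @ SC @ sol.Pi[i]
        assert np.linalg.norm(Pidot - rhs) < 1e-3 * max(np.linalg.norm(rhs), 1.0)


class TestMeanCost:
    def test_free_drift_is_zero(self, small_system):
        mu0 = np.array([1.0, -2.0, 0.5])
        muT = cb.transition_matrix(small_system, 1.0) @ mu0
        assert cb.mean_cost(small_system, mu0, muT, 1.0) < 1e-20

    def test_unit_brownian(self):
        sys_ = cb.LinearSystem(np.zeros((2, 2)), np.eye(2))
        assert cb.mean_cost(sys_, np.zeros(2), np.array([1.0, 0.0]), 1.0) == pytest.approx(1.0)

    def test_discretized_minimum_energy_oracle(self):
        sys_ = cb.make_random_stable_system(4, sparsity=0.2, seed=21)
        rng = np.random.default_rng(0)
        mu0, muT = rng.normal(size=4), rng.normal(size=4)
        ours = cb.mean_cost(sys_, mu0, muT, 1.0)
        oracle = min_energy_cost_discrete(sys_, mu0, muT, 1.0, dt=1e-3)
        assert abs(ours - oracle) / oracle < 0.005


class TestCovarianceCost:
    def test_uncontrolled_target_is_zero(self, small_system):
        ini = cb.GaussianState(np.zeros(3), cb.steady_state(small_system).sigma)
        tgt = cb.propagate_uncontrolled(small_system, ini, 1.0)
        sol = cb.solve_bridge(cb.BridgeProblem(small_system, ini, tgt, 1.0))
        assert abs(sol.J_cov) < 1e-8 * 3

    def test_two_form_identity(self, generic_problem, generic_solution):
        """The boundary-term form equals int tr(Pi S_C Pi Sigma) dt."""
        sol, prob = generic_solution, generic_problem
        SC = prob.system.S_C
        ts = sol.grid
        J1 = simpson(np.einsum("ij,tji->t", SC, sol.Pi), x=ts) - (
            np.trace(sol.Pi[-1] @ prob.target.sigma)
            - np.trace(sol.Pi[0] @ prob.initial.sigma)
        )
        J2 = simpson(
            np.einsum("tij,jk,tkl,tli->t", sol.Pi, SC, sol.Pi, sol.Sigma_t), x=ts
        )
        assert abs(J1 - J2) / abs(J1) < 1e-6

    def test_scalar_monte_carlo(self, scalar_system):
        ini = cb.GaussianState([0.0], [[1.0]])   # stationary variance of the fixture
        tgt = cb.GaussianState([0.0], [[1.8]])
        prob = cb.BridgeProblem(scalar_system, ini, tgt, 1.0)
        sol = cb.solve_bridge(prob)
        stats = cb.simulate_controlled_paths(prob, sol, n_paths=20_000,
                                             euler_dt=1.0 / 1500, seed=5)
        mc, se = stats.cost_mean_se()
        assert abs(mc - sol.J_total) < 3 * se

    def test_larger_target_and_shorter_horizon(self, scalar_system):
        """Doubling the uncontrolled endpoint variance costs something, and
        halving the horizon cannot make it cheaper (less time to diffuse)."""
        ini = cb.GaussianState([0.0], [[0.5]])
        sT = cb.propagate_uncontrolled(scalar_system, ini, 1.0).sigma[0, 0]
        tgt = cb.GaussianState([0.0], [[2 * sT]])
        J_full = cb.solve_bridge(cb.BridgeProblem(scalar_system, ini, tgt, 1.0)).J_cov
        J_half = cb.solve_bridge(cb.BridgeProblem(scalar_system, ini, tgt, 0.5)).J_cov
        assert J_full > 1e-3
        assert J_half >= J_full


class TestDecomposition:
    def test_additivity_and_invariances(self):
        rng = np.random.default_rng(8)
        sys_ = cb.make_random_stable_system(4, seed=8)
        mu_a, mu_b = rng.normal(size=4), rng.normal(size=4)
        cov_a = (rand_state(4, rng), rand_state(4, rng))
        cov_b = (rand_state(4, rng), rand_state(4, rng))

        def costs(mus, covs):
            prob = cb.BridgeProblem(
                sys_,
                cb.GaussianState(mus[0], covs[0].sigma),
                cb.GaussianState(mus[1], covs[1].sigma),
                1.0,
            )
            return cb.total_cost(prob, refine=False)

        Jm1, Jc1, Jt1 = costs((mu_a, mu_b), cov_a)
        Jm2, Jc2, _ = costs((mu_a, mu_b), cov_b)       # change covariances only
        Jm3, Jc3, _ = costs((mu_b, mu_a), cov_a)       # change means only
        assert Jt1 == Jm1 + Jc1
        assert abs(Jm1 - Jm2) <= 1e-9 * Jm1           # J_mean blind to covariances
        assert abs(Jc1 - Jc3) <= 1e-9 * Jc1           # J_cov blind to means
        assert Jc1 != Jc2 and Jm1 != Jm3

    def test_total_zero_for_uncontrolled_target(self, small_system):
        ini = cb.GaussianState(np.array([0.3, -0.1, 0.2]),
                               cb.steady_state(small_system).sigma)
        tgt = cb.propagate_uncontrolled(small_system, ini, 1.0)
        _, _, Jt = cb.total_cost(cb.BridgeProblem(small_system, ini, tgt, 1.0),
                                 refine=False)
        assert Jt < 1e-8


class TestMeanPath:
    def test_zero_means_zero_path(self):
        prob = random_bridge_problem(3, seed=31, zero_means=True)
        sol = cb.solve_bridge(prob)
        assert np.abs(sol.mu_t).max() < 1e-12
        assert np.abs(sol.m_t).max() < 1e-12

    def test_free_drift_feedforward_vanishes(self, small_system):
        mu0 = np.array([0.5, -0.3, 0.1])
        muT = cb.transition_matrix(small_system, 1.0) @ mu0
        rng = np.random.default_rng(2)
        prob = cb.BridgeProblem(
            small_system,
            cb.GaussianState(mu0, rand_state(3, rng).sigma),
            cb.GaussianState(muT, rand_state(3, rng).sigma),
            1.0,
        )
        sol = cb.solve_bridge(prob)
        ff = sol.m_t - np.einsum("tij,tj->ti", sol.Pi, sol.mu_t)
        assert np.abs(ff).max() < 1e-9

    def test_closed_loop_ode_hits_target(self, generic_problem):
        """Integrating d mu/dt = A mu - S_C (Pi mu - m) reproduces mu(t).

        Pi and m are linearly interpolated between grid points, so the check
        runs on a fine grid to keep interpolation error below the tolerance.
        """
        prob = generic_problem.with_grid(2000)
        sol = cb.solve_bridge(prob)
        A, SC = prob.system.A, prob.system.S_C
        ts = sol.grid

        def rhs(t, mu):
            j = min(np.searchsorted(ts, t, side="right") - 1, ts.size - 2)
            w = (t - ts[j]) / (ts[j + 1] - ts[j])
            Pk = (1 - w) * sol.Pi[j] + w * sol.Pi[j + 1]
            mk = (1 - w) * sol.m_t[j] + w * sol.m_t[j + 1]
            return A @ mu - SC @ (Pk @ mu - mk)

        out = solve_ivp(rhs, (0, prob.horizon), prob.initial.mu,
                        t_eval=ts, rtol=1e-9, atol=1e-11)
        assert np.linalg.norm(out.y[:, -1] - prob.target.mu) < 1e-6
        assert np.abs(out.y.T - sol.mu_t).max() < 1e-5


class TestNodeInputs:
    def test_zero_control_all_zero(self, small_system):
        ini = cb.GaussianState(np.zeros(3), cb.steady_state(small_system).sigma)
        tgt = cb.propagate_uncontrolled(small_system, ini, 1.0)
        prob = cb.BridgeProblem(small_system, ini, tgt, 1.0)
        im = cb.node_inputs(prob, cb.solve_bridge(prob))
        assert im.I_total.max() < 1e-10

    def test_identity_noise_sum_identity(self):
        """With S_C = I the node inputs sum to J_total."""
        rng = np.random.default_rng(4)
        A = cb.make_random_stable_system(4, seed=4).A
        sys_ = cb.LinearSystem(A, np.eye(4))
        prob = cb.BridgeProblem(
            sys_,
            cb.GaussianState(rng.normal(size=4), rand_state(4, rng).sigma),
            cb.GaussianState(rng.normal(size=4), rand_state(4, rng).sigma),
            1.0,
        )
        sol = cb.solve_bridge(prob)
        im = cb.node_inputs(prob, sol)
        assert abs(im.I_total.sum() - sol.J_total) / sol.J_total < 1e-6

    def test_additivity_exact(self, generic_problem, generic_solution):
        im = cb.node_inputs(generic_problem, generic_solution)
        assert np.array_equal(im.I_total, im.I_mean + im.I_cov)
        assert (im.I_total >= 0).all()


class TestInterfaces:
    def test_problem_roundtrip_and_export(self, tmp_path, generic_problem, generic_solution):
        back = cb.BridgeProblem.from_dict(generic_problem.to_dict())
        assert np.allclose(back.system.A, generic_problem.system.A)
        assert np.allclose(back.target.sigma, generic_problem.target.sigma)
        generic_solution.export(tmp_path / "sol")
        got = np.loadtxt(tmp_path / "sol" / "mu.tsv", delimiter="\t")
        assert np.allclose(got, generic_solution.mu_t)

    def test_grid_validation(self, small_system, zero_state):
        with pytest.raises(InvalidArgumentError):
            cb.BridgeProblem(small_system, zero_state(3), zero_state(3), 1.0,
                             grid=np.linspace(0, 1, 20))
        with pytest.raises(InvalidArgumentError):
            cb.BridgeProblem(small_system, zero_state(3), zero_state(3), -1.0)
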