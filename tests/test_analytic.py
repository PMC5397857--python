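"""MFA and LOP self-consistency solvers and the drifting-node density."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from netphase import (
    Network,
    SimConfig,
    drift_distribution,
    gilbert_random,
    largest_component,
    relative_phases,
    simulate,
    solve_lop,
    solve_mfa,
    wrap_phase,
)
from netphase.analytic import drift_phasor
from netphase.networks import degrees

OMEGA_10HZ = 2 * np.pi * 10.0


@pytest.fixture
def cfg() -> SimConfig:
    return SimConfig(coupling=5.0, noise_sd=0.0, duration_s=2.0,
                     transient_s=1.0, seed=0, n_runs=1)


class TestCompleteGraph:
    def test_mfa_uniform_solution(self, complete_network, cfg):
        sol = solve_mfa(complete_network, cfg, tol=1e-12)
        assert np.all(np.abs(sol.phi_star) < 1e-8)
        assert sol.global_R == pytest.approx(1.0, abs=1e-8)
        assert sol.locked.all()
        # frustration slows the collective rhythm below omega
        assert sol.omega < OMEGA_10HZ

    def test_lop_equals_mfa(self, complete_network, cfg):
        # the local field of every node is the global field here
        mfa = solve_mfa(complete_network, cfg, tol=1e-10)
        lop = solve_lop(complete_network, cfg, tol=1e-10)
        assert np.max(np.abs(lop.phi_star - mfa.phi_star)) < 1e-8
        assert lop.omega == pytest.approx(mfa.omega, abs=1e-8)
        assert np.max(np.abs(lop.local_r - mfa.global_R)) < 1e-8

    def test_zero_offset_gives_full_synchrony(self, complete_network):
        cfg0 = SimConfig(coupling=5.0, beta_rad=0.0, noise_sd=0.0,
                         duration_s=2.0, transient_s=1.0)
        for sol in (solve_mfa(complete_network, cfg0), solve_lop(complete_network, cfg0)):
            assert np.all(np.abs(sol.phi_star) < 1e-10)
            assert sol.omega == pytest.approx(OMEGA_10HZ, abs=1e-8)


class TestDegreePhaseMonotonicity:
    def test_hub_class_lags_leaf_class(self, two_class_network, cfg):
        for sol in (solve_mfa(two_class_network, cfg), solve_lop(two_class_network, cfg)):
            hub_phi = sol.phi_star[:4]
            leaf_phi = sol.phi_star[4:]
            assert hub_phi.max() < leaf_phi.min()

    def test_mfa_phase_nonincreasing_in_degree_exactly(self, cfg):
        # weighted ring-with-shortcuts: all degrees distinct
        rng = np.random.default_rng(5)
        n = 12
        A = rng.uniform(0.2, 1.0, (n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        net = Network(A)
        sol = solve_mfa(net, cfg)
        assert sol.locked.all()
        nj = degrees(net, "weighted")
        order = np.argsort(nj)
        assert np.all(np.diff(sol.phi_star[order]) <= 1e-12)
        assert spearmanr(nj, sol.phi_star).statistic == pytest.approx(-1.0)


class TestSelfConsistency:
    def test_mfa_order_parameter_reproduces_itself(self, two_class_network, cfg):
        sol = solve_mfa(two_class_network, cfg, tol=1e-10)
        Z = sol.node_phasor.mean()
        assert abs(Z.real - sol.global_R) < 1e-8
        assert abs(Z.imag) < 1e-8  # gauge Phi = 0

    def test_lop_local_fields_reproduce_themselves(self, two_class_network, cfg):
        sol = solve_lop(two_class_network, cfg, tol=1e-10)
        A = two_class_network.adjacency
        nj = degrees(two_class_network, "weighted")
        h = (A @ sol.node_phasor) / nj
        assert np.max(np.abs(np.abs(h) - sol.local_r)) < 1e-6
        assert np.max(np.abs(wrap_phase(np.angle(h) - sol.local_Theta))) < 1e-6
        assert abs(np.angle(sol.node_phasor.mean())) < 1e-6

    def test_converged_residual_below_tolerance(self, two_class_network, cfg):
        sol = solve_lop(two_class_network, cfg, tol=1e-9)
        assert sol.residual < 1e-6

    def test_lop_cold_start_agrees_with_warm_start(self, two_class_network, cfg):
        ref = solve_lop(two_class_network, cfg, init="mfa")
        alt = solve_lop(two_class_network, cfg, init="zero")
        assert np.max(np.abs(wrap_phase(alt.phi_star - ref.phi_star))) < 1e-6

    def test_lop_random_start_reaches_a_valid_fixed_point(self, two_class_network, cfg):
        # random initial phasors may land in a different basin (e.g. the
        # mirror state), but whatever is returned must be self-consistent
        sol = solve_lop(two_class_network, cfg, init="random")
        assert sol.residual < 1e-6


class TestRegimesAndErrors:
    def test_uncoupled_network_reported_incoherent(self, two_class_network):
        cfg = SimConfig(coupling=0.0, duration_s=2.0, transient_s=1.0)
        sol = solve_mfa(two_class_network, cfg)
        assert sol.global_R == 0.0
        assert not sol.locked.any()

    def test_locking_criterion_matches_flags(self, two_class_network):
        # detune one leaf far enough to break its lock
        freqs = np.full(16, 10.0)
        freqs[-1] = 10.6
        cfg = SimConfig(coupling=5.0, freq_hz=freqs, duration_s=2.0, transient_s=1.0)
        sol = solve_lop(two_class_network, cfg)
        nj = degrees(two_class_network, "weighted")
        K = cfg.coupling / 16 * nj * sol.local_r
        delta = cfg.omega(16) - sol.omega
        assert np.array_equal(sol.locked, K > np.abs(delta))
        assert not sol.locked[-1]

    def test_non_convergence_raises_with_residual(self, two_class_network, cfg):
        with pytest.raises(RuntimeError, match="did not converge"):
            solve_lop(two_class_network, cfg, max_iter=2)
        with pytest.raises(RuntimeError, match="did not converge"):
            solve_mfa(two_class_network, cfg, max_iter=1)


class TestLopDominance:
    def test_lop_tracks_simulation_at_least_as_well_as_mfa(self):
        net = largest_component(gilbert_random(60, 0.1, seed=2))
        sim_cfg = SimConfig(coupling=5.0, noise_sd=0.0, dt_s=2e-3,
                            duration_s=180.0, transient_s=150.0, seed=5, n_runs=1)
        traj = simulate(net, sim_cfg)
        _, phi = relative_phases(traj)
        rho_mfa = spearmanr(solve_mfa(net, sim_cfg).phi_star, phi).statistic
        rho_lop = spearmanr(solve_lop(net, sim_cfg).phi_star, phi).statistic
        assert rho_lop >= rho_mfa
        assert rho_lop > 0.85


class TestDriftDistribution:
    @pytest.fixture
    def core_leaf(self):
        """Synchronised 5-clique plus one weakly attached, detuned leaf."""
        n = 6
        A = np.ones((n, n))
        np.fill_diagonal(A, 0.0)
        A[5, :] = 0.0
        A[:, 5] = 0.0
        A[5, 0] = A[0, 5] = 1.0
        freqs = np.full(n, 10.0)
        freqs[5] = 10.5
        net = Network(A)
        cfg = SimConfig(coupling=5.0, freq_hz=freqs, noise_sd=0.0,
                        duration_s=360.0, transient_s=60.0, seed=8, n_runs=1)
        return net, cfg

    def test_density_normalised(self, core_leaf):
        net, cfg = core_leaf
        sol = solve_lop(net, cfg)
        assert not sol.locked[5]
        grid, dens, _ = drift_distribution(5, sol, cfg, grid_size=400)
        assert np.sum(dens) * (2 * np.pi / 400) == pytest.approx(1.0, abs=1e-6)

    def test_locked_node_rejected(self, core_leaf):
        net, cfg = core_leaf
        sol = solve_lop(net, cfg)
        with pytest.raises(ValueError, match="phi_star"):
            drift_distribution(0, sol, cfg)

    def test_mass_concentrates_near_locking_boundary(self):
        # directly exercise the density at K -> |Delta|^-
        delta, K, beta = 1.0, 0.999, 0.1
        grid = -np.pi + 2 * np.pi * np.arange(1, 2001) / 2000
        dens = 1.0 / np.abs(delta + K * np.sin(-grid - beta))
        dens /= dens.sum() * (2 * np.pi / 2000)
        peak = grid[np.argmax(dens)]
        would_lock = -beta + np.arcsin(1.0)  # phase the node would lock at
        assert abs(wrap_phase(peak - would_lock)) < 0.05
        # more than half the mass within 0.5 rad of the tangency
        near = np.abs(wrap_phase(grid - would_lock)) < 0.5
        assert dens[near].sum() / dens.sum() > 0.5

    def test_closed_form_phasor_matches_grid_average(self):
        delta, K, Theta, beta = 2.0, 0.8, 0.3, 0.25
        z = drift_phasor(delta, K, Theta, beta)
        grid = -np.pi + 2 * np.pi * np.arange(1, 20001) / 20000
        dens = 1.0 / np.abs(delta + K * np.sin(Theta - grid - beta))
        dens /= dens.sum()
        z_num = (dens * np.exp(1j * grid)).sum()
        assert abs(z - z_num) < 1e-6

    def test_long_simulation_histogram_matches_density(self, core_leaf):
        # total-variation distance between the simulated phase histogram of
        # the drifting leaf and the frozen-field analytic density
        net, cfg = core_leaf
        sol = solve_lop(net, cfg)
        traj = simulate(net, cfg)
        # anchor the gauge to the locked core instead of the wobbling mean
        psi = wrap_phase(traj.phases[5] - traj.phases[0] + sol.phi_star[0])
        nbins = 36
        edges = np.linspace(-np.pi, np.pi, nbins + 1)
        hist, _ = np.histogram(psi, bins=edges, density=False)
        p_sim = hist / hist.sum()
        grid, dens, _ = drift_distribution(5, sol, cfg, grid_size=7200)
        p_ana = np.zeros(nbins)
        bin_idx = np.clip(np.digitize(grid, edges) - 1, 0, nbins - 1)
        np.add.at(p_ana, bin_idx, dens)
        p_ana /= p_ana.sum()
        tv = 0.5 * np.abs(p_sim - p_ana).sum()
        assert tv < 0.1
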