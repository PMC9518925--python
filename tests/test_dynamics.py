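"""gLV integration, noise, perturbations, sampling and two-species analytics."""

import numpy as np
import pytest

from glvnet.dynamics import (
    PerturbationSpec,
    ProcessNoiseSpec,
    SimulationSettings,
    check_survival,
    coexistence_region,
    glv_rhs,
    sample_abundances,
    simulate,
    simulate_ensemble,
    two_species_equilibrium,
)
from glvnet.networks import TopologySpec, sample_community, sample_host_ensemble

K12 = (1.5, 1.1)  # the two-species reference capacities
R12 = (1.0, 2.0)


def _two_species_A(a12, a21):
    return np.array([[0.0, a12], [a21, 0.0]])


class TestRHS:
    def test_zero_abundance_zero_derivative(self):
        out = glv_rhs(np.zeros(3), np.ones(3), np.ones(3), np.zeros((3, 3)))
        np.testing.assert_array_equal(out, 0.0)

    def test_logistic_fixed_point(self):
        out = glv_rhs(np.array([2.0]), np.array([1.3]), np.array([2.0]), np.zeros((1, 1)))
        assert out[0] == pytest.approx(0.0, abs=1e-14)

    def test_hand_computed_example(self):
        # dN1 = 1*1*(1 - 1/1.5 + 0.2) = 0.5333..., dN2 = 2*1*(1 - 1/1.1 - 0.3)
        out = glv_rhs(
            np.ones(2), np.array(R12), np.array(K12), _two_species_A(0.2, -0.3)
        )
        np.testing.assert_allclose(out, [8 / 15, 2 * (1 - 1 / 1.1 - 0.3)], rtol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            glv_rhs(np.array([np.nan, 1.0]), np.ones(2), np.ones(2), np.zeros((2, 2)))


class TestSimulate:
    def test_decoupled_species_reach_their_capacities(self, rng):
        r = rng.uniform(0.05, 0.1, 6)
        K = rng.uniform(0.2, 1.0, 6)
        traj = simulate(
            r, K, np.zeros((6, 6)), SimulationSettings(rtol=1e-8, atol=1e-11)
        )
        np.testing.assert_allclose(traj.abundances[-1], K, atol=1e-6)
        assert traj.converged and traj.survived

    def test_two_species_matches_closed_form(self):
        settings = SimulationSettings(horizon=500.0, rtol=1e-10, atol=1e-12)
        eq = two_species_equilibrium(*K12, 0.2, 0.3)
        traj = simulate(np.array(R12), np.array(K12), _two_species_A(0.2, 0.3), settings)
        np.testing.assert_allclose(traj.abundances[-1], [eq.n1, eq.n2], atol=1e-6)

    def test_zero_process_noise_is_bitwise_deterministic(self):
        r, K = np.array(R12), np.array(K12)
        A = _two_species_A(0.1, -0.2)
        settings = SimulationSettings(horizon=50.0)
        plain = simulate(r, K, A, settings)
        with_spec = simulate(
            r, K, A, settings, process_noise=ProcessNoiseSpec(sigma=0.0),
            rng=np.random.default_rng(0),
        )
        np.testing.assert_array_equal(plain.abundances, with_spec.abundances)

    def test_process_noise_perturbs_path_but_stays_positive(self):
        r, K = np.array(R12), np.array(K12)
        A = _two_species_A(0.1, -0.2)
        settings = SimulationSettings(horizon=50.0)
        noisy = simulate(
            r, K, A, settings, process_noise=ProcessNoiseSpec(sigma=0.1),
            rng=np.random.default_rng(1),
        )
        plain = simulate(r, K, A, settings)
        assert np.max(np.abs(noisy.abundances - plain.abundances)) > 1e-3
        assert np.all(noisy.abundances > 0)

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(ValueError):
            simulate(
                np.ones(2), np.ones(2), np.zeros((2, 2)), n0=np.array([0.0, 1.0])
            )


class TestPerturbation:
    def test_recovery_to_original_equilibrium(self):
        # capacities are redrawn during the window and restored afterwards;
        # by the horizon the community is back at its unperturbed equilibrium
        rng = np.random.default_rng(5)
        c = sample_community(topology=TopologySpec(n_species=6, density=0.25), rng=rng)
        settings = SimulationSettings(horizon=1000.0)
        plain = simulate(c.r, c.K, c.A, settings)
        pert = simulate(
            c.r, c.K, c.A, settings,
            perturbation=PerturbationSpec(start=175.0, duration=50.0),
            rng=np.random.default_rng(6),
        )
        during = np.abs(pert.at(200.0) - plain.at(200.0)).max()
        final = np.abs(pert.abundances[-1] - plain.abundances[-1]).max()
        assert during > 1e-3  # the window visibly displaces the state
        assert final < 1e-6


class TestSurvival:
    def test_threshold_is_strictly_below(self):
        times = np.arange(3.0)
        from glvnet.dynamics import Trajectory

        ok = Trajectory(times, np.full((3, 2), 0.001), True, True)
        assert check_survival(ok, 0.001)
        dip = Trajectory(times, np.array([[1, 1], [1, 0.0005], [1, 1.0]]), True, True)
        assert not check_survival(dip, 0.001)

    def test_competitive_exclusion_detected(self):
        # 1 + a12*K2 < 0 makes N1* <= 0: species 1 must cross the threshold
        a12 = -1.2  # 1 + (-1.2)(1.1) < 0
        traj = simulate(
            np.array(R12), np.array(K12), _two_species_A(a12, -0.1),
            SimulationSettings(horizon=500.0),
        )
        assert not check_survival(traj, 0.001)

    def test_ignore_window_excludes_recorded_times(self):
        from glvnet.dynamics import Trajectory

        times = np.arange(5.0)
        ab = np.ones((5, 1))
        ab[2, 0] = 1e-5  # dip at t=2 only
        traj = Trajectory(times, ab, True, True)
        assert not check_survival(traj, 0.001)
        assert check_survival(traj, 0.001, ignore_window=(1.5, 2.5))


class TestSampling:
    def _ensemble_traj(self, rng, n_hosts=8):
        c = sample_community(topology=TopologySpec(n_species=4, density=0.25), rng=rng)
        hosts = sample_host_ensemble(c, n_hosts, 0.25, 0, 0, rng)
        return simulate_ensemble(hosts, SimulationSettings(horizon=200.0))

    def test_zero_noise_returns_exact_values(self, rng):
        traj = self._ensemble_traj(rng)
        s = sample_abundances(traj, 150.0, upsilon=0.0, rng=rng)
        np.testing.assert_array_equal(s.matrix, traj.at(150.0))

    def test_noise_bounded_by_half_width(self, rng):
        traj = self._ensemble_traj(rng)
        s = sample_abundances(traj, 150.0, upsilon=0.01, rng=rng)
        assert np.abs(s.matrix - traj.at(150.0)).max() <= 0.01

    def test_noise_moments(self, rng):
        # U(-v, v): mean 0, variance v^2/3
        traj = self._ensemble_traj(rng, n_hosts=4)
        noise = np.concatenate(
            [
                (sample_abundances(traj, 100.0, 0.01, rng).matrix - traj.at(100.0)).ravel()
                for _ in range(7000)
            ]
        )
        assert noise.mean() == pytest.approx(0.0, abs=3e-5)
        assert noise.var() == pytest.approx(0.01**2 / 3, rel=0.02)

    def test_out_of_range_timepoint_rejected(self, rng):
        traj = self._ensemble_traj(rng)
        with pytest.raises(ValueError):
            sample_abundances(traj, 10_000.0, 0.01, rng)

    def test_random_policy_stays_in_window(self, rng):
        traj = self._ensemble_traj(rng)
        s = sample_abundances(
            traj, "random", 0.0, rng, random_window=(100.0, 200.0)
        )
        assert np.all((s.times >= 100.0) & (s.times <= 200.0))
        assert len(np.unique(s.times)) > 1  # per-host times differ


class TestTwoSpeciesAnalytics:
    def test_decoupled_limit(self):
        eq = two_species_equilibrium(*K12, 0.0, 0.0)
        assert (eq.n1, eq.n2) == K12 and eq.coexists

    def test_one_sided_interaction_leaves_partner_at_K(self):
        # amensalism/commensalism on species 1: species 2 sits exactly at K2
        for a12 in (-0.3, 0.4):
            eq = two_species_equilibrium(*K12, a12, 0.0)
            assert eq.n2 == K12[1]

    def test_matches_numerical_integration(self):
        eq = two_species_equilibrium(*K12, 0.2, 0.3)
        traj = simulate(
            np.array(R12), np.array(K12), _two_species_A(0.2, 0.3),
            SimulationSettings(horizon=500.0, rtol=1e-10, atol=1e-12),
        )
        np.testing.assert_allclose(traj.abundances[-1], [eq.n1, eq.n2], atol=1e-6)

    def test_singular_denominator_flagged(self):
        # K1*K2 = 1 and a12 = a21 = 1 makes the denominator exactly zero
        eq = two_species_equilibrium(2.0, 0.5, 1.0, 1.0)
        assert not eq.coexists and np.isnan(eq.n1)

    def test_region_contains_origin_excludes_exclusion(self):
        grid = np.linspace(-1.0, 1.0, 11)
        field = coexistence_region(grid, grid, *K12)
        assert field[5, 5]  # origin
        assert not field[0, 5]  # a12 = -1: 1 + a12*K2 < 0

    def test_region_verdicts_agree_with_simulation(self):
        # survival of the integrated model is the independent oracle
        grid = np.linspace(-0.6, 0.6, 7)
        field = coexistence_region(grid, grid, *K12)
        settings = SimulationSettings(horizon=800.0)
        for i, a12 in enumerate(grid):
            for j, a21 in enumerate(grid):
                traj = simulate(
                    np.array(R12), np.array(K12), _two_species_A(a12, a21), settings
                )
                assert check_survival(traj, 0.001) == field[i, j], (a12, a21)
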