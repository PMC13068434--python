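"""Kuramoto integration oracles, order parameter, PLV, rate readouts."""

import numpy as np
import pytest

import gammatongue as gt
from gammatongue.oscillator_dynamics import (
    PhaseTrajectory,
    TrialConfig,
    _plv_from_phases,
    instantaneous_frequency,
)


def traj_from(theta, times, omega=None):
    theta = np.asarray(theta, dtype=float)
    return PhaseTrajectory(
        times=np.asarray(times, dtype=float),
        theta=theta,
        omega=omega if omega is not None else np.zeros(theta.shape[1]),
    )


class TestOrderParameter:
    def test_coherent_phases_give_unity(self):
        r, _psi = gt.order_parameter(np.full(7, 1.3))
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_antiphase_pair_cancels(self):
        r, _ = gt.order_parameter(np.array([0.0, np.pi]))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_pair(self):
        r, psi = gt.order_parameter(np.array([0.0, np.pi / 2]))
        assert r == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
        assert psi == pytest.approx(np.pi / 4, abs=1e-12)

    def test_global_phase_shift_invariance(self, rng):
        phases = rng.uniform(0, 2 * np.pi, 50)
        r1, _ = gt.order_parameter(phases)
        r2, _ = gt.order_parameter(phases + 1.234)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            gt.order_parameter(np.array([]))


class TestTrialIntegration:
    def test_uncoupled_oscillators_drift_linearly(self, rng):
        omega = rng.uniform(150, 320, 5)
        theta0 = rng.uniform(0, 2 * np.pi, 5)
        traj = gt.simulate_trial(omega, np.zeros((5, 5)), theta0=theta0)
        expected = theta0[None, :] + omega[None, :] * traj.times[:, None]
        assert np.max(np.abs(traj.theta - expected)) < 1e-5

    def test_identical_frequencies_synchronize(self, rng):
        N = 12
        omega = np.full(N, 2 * np.pi * 30.0)
        K = np.full((N, N), 8.0)
        np.fill_diagonal(K, 0.0)
        theta0 = rng.uniform(0, 2 * np.pi, N)
        traj = gt.simulate_trial(omega, K, theta0=theta0)
        r0, _ = gt.order_parameter(traj.theta[0])
        r1, _ = gt.order_parameter(traj.theta[-1])
        assert r1 > r0
        assert r1 > 0.99

    def test_two_oscillator_locking_matches_adler_boundary(self):
        """Phase locking iff |delta_omega| <= K12 for N = 2 (Adler equation).

        With dtheta_i = omega_i + (K12/N) sin(theta_j - theta_i), the phase
        difference obeys d(dphi) = delta_omega - 2*(K12/N) sin(dphi), which
        locks exactly when |delta_omega| <= 2 K12 / N = K12.
        """
        K12 = 10.0
        K = np.array([[0.0, K12], [K12, 0.0]])
        cfg = TrialConfig(duration=3.0)
        locked = []
        deltas = np.linspace(2.0, 18.0, 9)
        for d in deltas:
            omega = np.array([200.0 + d / 2, 200.0 - d / 2])
            traj = gt.simulate_trial(omega, K, cfg, theta0=np.zeros(2))
            dphi = traj.theta[:, 0] - traj.theta[:, 1]
            tail = dphi[traj.times > 2.0]
            locked.append(np.ptp(tail) < 0.1)
        # boundary at |delta| = K12 = 10, grid step 2
        for d, l in zip(deltas, locked):
            if d <= K12 - 2:
                assert l, f"expected locking at detuning {d}"
            if d >= K12 + 2:
                assert not l, f"expected drift at detuning {d}"

    def test_initial_phase_2pi_shift_leaves_observables_unchanged(self, rng):
        # strong coupling vs small detuning: locked state, exponentially
        # stable, so the comparison is not washed out by chaotic sensitivity
        N = 6
        omega = 200.0 + rng.uniform(-1.5, 1.5, N)
        K = np.full((N, N), 8.0)
        np.fill_diagonal(K, 0.0)
        theta0 = rng.uniform(0, 2 * np.pi, N)
        t1 = gt.simulate_trial(omega, K, theta0=theta0)
        shift = np.zeros(N)
        shift[0] = 2 * np.pi
        t2 = gt.simulate_trial(omega, K, theta0=theta0 + shift)
        r1, _ = gt.order_parameter(t1.theta[-1])
        r2, _ = gt.order_parameter(t2.theta[-1])
        assert r1 == pytest.approx(r2, abs=1e-6)
        assert gt.pairwise_plv(t1)[0, 1] == pytest.approx(
            gt.pairwise_plv(t2)[0, 1], abs=1e-6
        )

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            gt.simulate_trial(np.array([np.nan, 1.0]), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            gt.simulate_trial(np.ones(2), np.full((2, 2), np.inf))


class TestTrialSynchrony:
    def test_locked_trajectory_gives_unity(self):
        times = np.linspace(0, 1, 1001)
        theta = np.tile(2 * np.pi * 30 * times[:, None], (1, 4))
        s = gt.trial_synchrony(traj_from(theta, times))
        assert s.r_mean == pytest.approx(1.0, abs=1e-9)

    def test_incoherent_population_scales_as_inverse_sqrt_n(self, rng):
        # K = 0 and wide frequency spread: E[r] ~ sqrt(pi)/(2 sqrt(N))
        N = 400
        vals = []
        for _ in range(10):
            phases = rng.uniform(0, 2 * np.pi, (60, N))
            r, _ = gt.order_parameter(phases)
            vals.append(r.mean())
        expected = np.sqrt(np.pi) / 2 / np.sqrt(N)
        assert np.mean(vals) == pytest.approx(expected, rel=0.15)

    def test_averages_second_half_only(self):
        times = np.linspace(0, 1, 1001)
        # desynchronized first half, coherent second half
        theta = np.zeros((1001, 2))
        theta[times <= 0.5, 1] = np.pi
        s = gt.trial_synchrony(traj_from(theta, times))
        assert s.r_mean == pytest.approx(1.0)


class TestPairwisePlv:
    def test_constant_offset_gives_unity(self):
        times = np.linspace(0, 1, 1001)
        base = 2 * np.pi * 30 * times
        theta = np.column_stack([base, base + 0.7])
        plv = gt.pairwise_plv(traj_from(theta, times))
        assert plv[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert plv.diagonal() == pytest.approx(1.0)

    def test_integer_cycle_drift_cancels(self):
        # relative drift covering exactly k full cycles over the window
        cfg = TrialConfig(subsample_points=50)
        times = np.linspace(0, 1, 1001)
        k = 2
        drift = 2 * np.pi * k * 50 / 49  # full cycles across the 50 samples
        theta = np.column_stack([np.zeros_like(times), drift * times])
        plv = gt.pairwise_plv(traj_from(theta, times), cfg)
        assert plv[0, 1] < 0.05

    def test_random_phases_rayleigh_scale(self, rng):
        # independent phases per timepoint: E[PLV] ~ sqrt(pi)/(2 sqrt(T))
        T = 50
        vals = [
            _plv_from_phases(rng.uniform(0, 2 * np.pi, (T, 2)))[0, 1]
            for _ in range(4000)
        ]
        assert np.mean(vals) == pytest.approx(np.sqrt(np.pi) / 2 / np.sqrt(T), rel=0.05)

    def test_symmetric_unit_interval(self, rng):
        theta = rng.uniform(0, 2 * np.pi, (50, 6))
        plv = _plv_from_phases(theta)
        assert np.allclose(plv, plv.T)
        assert plv.min() >= 0.0 and plv.max() <= 1.0


class TestRateReadouts:
    def test_uncoupled_rate_equals_mean_frequency(self, rng):
        nu = rng.uniform(25, 50, 8)
        omega = 2 * np.pi * nu
        traj = gt.simulate_trial(omega, np.zeros((8, 8)), theta0=np.zeros(8))
        out = gt.rate_readouts(traj, nu)
        assert out.figure_rate == pytest.approx(nu.mean(), rel=1e-6)
        assert out.rate_difference == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_coupling_leaves_population_rate_pinned(self, rng):
        # antisymmetry of sin(theta_j - theta_i) cancels in the population mean
        N = 10
        nu = rng.uniform(25, 50, N)
        K = rng.uniform(0, 15, (N, N))
        K = (K + K.T) / 2
        np.fill_diagonal(K, 0)
        traj = gt.simulate_trial(
            2 * np.pi * nu, K, theta0=rng.uniform(0, 2 * np.pi, N)
        )
        out = gt.rate_readouts(traj, nu)
        assert out.figure_rate == pytest.approx(nu.mean(), rel=1e-3)

    def test_instantaneous_frequency_of_linear_drift(self):
        times = np.linspace(0, 1, 1001)
        theta = 2 * np.pi * 33.0 * times[:, None]
        f = instantaneous_frequency(traj_from(theta, times))
        assert np.allclose(f, 33.0)


class TestSessionRunner:
    def test_session_trial_count(self, small_simulator, small_sheet):
        K = gt.initial_coupling(small_sheet).K
        res = small_simulator.run_session(K, session=1, blocks=2)
        assert len(res.records) == 2 * 25  # blocks x conditions
        assert res.tongue.values.shape == (5, 5)

    def test_single_block_single_condition_tongue(self, small_sheet):
        sim = gt.SessionSimulator(
            sheet=small_sheet,
            conditions=[gt.StimulusCondition(zeta=0.2, rho=1.0, zeta_level=0, rho_level=0)],
            seed=5,
        )
        K = gt.initial_coupling(small_sheet).K
        res = sim.run_session(K, session=1, blocks=1)
        assert res.tongue.values.shape == (1, 1)
        assert res.tongue.values[0, 0] == pytest.approx(res.records.r_mean.iloc[0])

    def test_streamed_experience_matches_collected_plvs(self, small_simulator, small_sheet):
        K = gt.initial_coupling(small_sheet).K
        w = lambda r: 0.3 + 0.5 * r  # noqa: E731
        res_a = small_simulator.run_session(K, session=2, blocks=1, collect_plv=True)
        res_b = small_simulator.run_session(K, session=2, blocks=1, plv_weight_fn=w)
        Q_manual = sum(w(r) * plv.astype(float) for r, plv in res_a.plv_trials)
        Q_manual /= sum(w(r) for r, _ in res_a.plv_trials)
        np.testing.assert_allclose(
            res_b.q_weighted_sum / res_b.q_weight_total, Q_manual, atol=1e-6
        )

    def test_session_reproducible_under_fixed_seed(self, small_sheet):
        K = gt.initial_coupling(small_sheet).K
        r1 = gt.SessionSimulator(sheet=small_sheet, seed=9).run_session(K, 1, blocks=1)
        r2 = gt.SessionSimulator(sheet=small_sheet, seed=9).run_session(K, 1, blocks=1)
        np.testing.assert_array_equal(r1.tongue.values, r2.tongue.values)
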