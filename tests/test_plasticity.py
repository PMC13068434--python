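"""Psychometric link, Hebbian experience accumulation, learning-rate search."""

import numpy as np
import pytest

import gammatongue as gt
from gammatongue.plasticity import (
    LearningConfig,
    LearningRateFit,
    PsychometricParams,
    estimate_learning_rate,
    learning_rate_objective,
)
from gammatongue.tongue_metrics import ArnoldTongue


def tongue(values, kind="synchrony"):
    values = np.asarray(values, dtype=float)
    return ArnoldTongue(
        values=values,
        zeta_axis=np.linspace(0.01, 1, values.shape[0]),
        rho_axis=np.linspace(1, 1.5, values.shape[1]),
        kind=kind,
    )


class TestProbCorrect:
    def test_midpoint(self):
        p = gt.prob_correct(0.5, PsychometricParams(mu0=-1.0, mu1=2.0))
        assert p == pytest.approx(0.5)

    def test_flat_when_slope_zero(self):
        params = PsychometricParams(mu0=0.7, mu1=0.0)
        r = np.linspace(0, 1, 5)
        p = gt.prob_correct(r, params)
        assert np.allclose(p, 1 / (1 + np.exp(-0.7)))

    def test_hand_value(self):
        p = gt.prob_correct(0.5, PsychometricParams(mu0=0.0, mu1=2.0))
        assert p == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)

    def test_monotone_in_synchrony(self):
        params = PsychometricParams(mu0=-2.0, mu1=6.0)
        p = gt.prob_correct(np.linspace(0, 1, 20), params)
        assert np.all(np.diff(p) > 0)


class TestFitPsychometric:
    def test_recovery_from_generated_accuracies(self, rng):
        true = PsychometricParams(mu0=-1.2, mu1=4.5)
        r = rng.uniform(0.05, 0.95, 25).reshape(5, 5)
        p = gt.prob_correct(r, true)
        n = 2000
        acc = rng.binomial(n, p) / n
        fit = gt.fit_psychometric(tongue(r), tongue(acc, "accuracy"), n)
        assert abs(fit.mu0 - true.mu0) < 2 * fit.se[0]
        assert abs(fit.mu1 - true.mu1) < 2 * fit.se[1]

    def test_null_slope_when_accuracy_independent_of_synchrony(self, rng):
        r = rng.uniform(0, 1, 25).reshape(5, 5)
        acc = np.full((5, 5), 0.7)
        fit = gt.fit_psychometric(tongue(r), tongue(acc, "accuracy"), 500)
        assert abs(fit.mu1) < 2.5 * fit.se[1]

    def test_degenerate_accuracy_flagged(self):
        r = np.linspace(0, 1, 25).reshape(5, 5)
        with pytest.raises(RuntimeError):
            gt.fit_psychometric(tongue(r), tongue(np.ones((5, 5)), "accuracy"), 100)

    def test_perfect_separation_flagged(self):
        r = np.linspace(0, 1, 25).reshape(5, 5)
        acc = (r > 0.5).astype(float)
        with pytest.raises(RuntimeError):
            gt.fit_psychometric(tongue(r), tongue(acc, "accuracy"), 1000)


class TestExperienceAccumulation:
    def test_single_trial_returns_its_plv(self):
        plv = np.array([[1.0, 0.4], [0.4, 1.0]])
        Q = gt.accumulate_experience([plv], [0.8], PsychometricParams(-1, 5))
        np.testing.assert_allclose(Q.Q, plv)

    def test_uniform_weights_reduce_to_plain_mean(self):
        p1 = np.full((2, 2), 0.2)
        p2 = np.full((2, 2), 0.6)
        Q = gt.accumulate_experience([p1, p2], [0.5, 0.5], PsychometricParams(0, 0))
        np.testing.assert_allclose(Q.Q, 0.4)

    def test_hand_weighted_average(self):
        # two trials with unequal P_c weights at a single entry
        p1 = np.full((1, 1), 0.2)
        p2 = np.full((1, 1), 0.6)
        params = PsychometricParams(mu0=-2.0, mu1=4.0)
        w1 = gt.prob_correct(0.1, params)
        w2 = gt.prob_correct(0.9, params)
        Q = gt.accumulate_experience([p1, p2], [0.1, 0.9], params)
        assert Q.Q[0, 0] == pytest.approx((w1 * 0.2 + w2 * 0.6) / (w1 + w2), abs=1e-12)

    def test_entries_stay_in_unit_interval(self, rng):
        plvs = [rng.uniform(0, 1, (4, 4)) for _ in range(6)]
        Q = gt.accumulate_experience(plvs, rng.uniform(0, 1, 6), PsychometricParams(-1, 3))
        assert Q.Q.min() >= 0 and Q.Q.max() <= 1


class TestCouplingUpdate:
    def test_zero_learning_rate_is_identity(self, rng):
        K = rng.uniform(0, 20, (5, 5))
        K = (K + K.T) / 2
        Q = rng.uniform(0, 1, (5, 5))
        out = gt.update_coupling(K, Q, gamma=24.63, E=0.0)
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(out.K[off], K[off])

    def test_infinite_learning_reaches_functional_coupling(self, rng):
        K = rng.uniform(0, 20, (4, 4))
        Q = rng.uniform(0, 1, (4, 4))
        Q = (Q + Q.T) / 2
        out = gt.update_coupling(K, Q, gamma=24.63, E=50.0)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(out.K[off], 24.63 * Q[off], rtol=1e-12)

    def test_ln2_learning_is_midpoint(self, rng):
        K = rng.uniform(0, 20, (4, 4))
        Q = rng.uniform(0, 1, (4, 4))
        out = gt.update_coupling(K, Q, gamma=10.0, E=np.log(2))
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(out.K[off], (K[off] + 10.0 * Q[off]) / 2, rtol=1e-12)

    def test_coupling_bounded_over_many_sessions(self, rng):
        gamma = 24.63
        K = rng.uniform(0, gamma, (6, 6))
        K = (K + K.T) / 2
        for _ in range(50):
            Q = rng.uniform(0, 1, (6, 6))
            Q = (Q + Q.T) / 2
            K = gt.update_coupling(K, Q, gamma, E=rng.uniform(0, 3)).K
            assert K.min() >= 0 and K.max() <= gamma + 1e-9

    def test_negative_learning_rate_rejected(self):
        with pytest.raises(ValueError):
            gt.update_coupling(np.zeros((2, 2)), np.zeros((2, 2)), 1.0, -0.1)


class SurrogateSession:
    """Cheap differentiable stand-in for the session-2 simulator.

    Maps a coupling matrix to a synchrony tongue through a smooth monotone
    function of mean coupling, peaking at a known target E.
    """

    def __init__(self, K1, Q1, gamma, target_E, behavior):
        self.K1, self.Q1, self.gamma = K1, Q1, gamma
        target_K = gt.update_coupling(K1, Q1, gamma, target_E).K
        self.target_mean = target_K.mean()
        self.normalized = gt.minmax_normalize(behavior)

    def __call__(self, K2):
        # exactly reproduces the normalized behavior map at the target E,
        # degrading smoothly away from it
        err = abs(K2.K.mean() - self.target_mean) / self.gamma
        vals = np.clip(self.normalized.values - err, 0.0, 1.0)
        return tongue(vals)


class TestLearningRateSearch:
    def setup_method(self):
        rng = np.random.default_rng(11)
        K1 = rng.uniform(0, 10, (6, 6))
        self.K1 = (K1 + K1.T) / 2
        Q1 = rng.uniform(0.4, 1, (6, 6))
        self.Q1 = (Q1 + Q1.T) / 2
        self.gamma = 24.63
        self.behavior = tongue(
            np.clip(rng.uniform(0.4, 1, (5, 5)), 0, 1), kind="accuracy"
        )

    def test_recovers_known_learning_rate(self):
        target = 0.8
        sim = SurrogateSession(self.K1, self.Q1, self.gamma, target, self.behavior)
        fit = estimate_learning_rate(self.behavior, sim, self.K1, self.Q1, self.gamma)
        assert fit.E == pytest.approx(target, rel=0.05)

    def test_nested_search_beats_or_matches_coarse_grid(self):
        sim = SurrogateSession(self.K1, self.Q1, self.gamma, 0.37, self.behavior)
        fit = estimate_learning_rate(self.behavior, sim, self.K1, self.Q1, self.gamma)
        # brute force over every candidate the search visited
        best = max(fit.history.objective)
        assert fit.objective == pytest.approx(best, abs=1e-12)
        # and matches exhaustive evaluation over the visited union
        vals = [
            learning_rate_objective(
                self.behavior,
                sim(gt.update_coupling(self.K1, self.Q1, self.gamma, E)),
            )
            for E in fit.history.E
        ]
        assert fit.objective == pytest.approx(max(vals), abs=1e-12)

    def test_unchanged_behavior_selects_near_minimum(self):
        # objective flat-optimal at E -> 0: no improvement from learning
        def sim_flat(K2):
            return tongue(self.behavior.values * 0 + 0.5)

        cfg = LearningConfig()
        fit = estimate_learning_rate(
            self.behavior, sim_flat, self.K1, self.Q1, self.gamma, cfg
        )
        assert fit.E == pytest.approx(cfg.e_min)  # ties break to smallest E

    def test_search_history_has_expected_size(self):
        sim = SurrogateSession(self.K1, self.Q1, self.gamma, 1.0, self.behavior)
        cfg = LearningConfig()
        fit = estimate_learning_rate(self.behavior, sim, self.K1, self.Q1, self.gamma, cfg)
        assert len(fit.history) == cfg.grid_levels * cfg.candidates_per_grid
        assert isinstance(fit, LearningRateFit)


class TestLearningTrajectoryProperties:
    def test_couplings_stay_bounded_through_learning(self, small_simulator, small_sheet):
        from gammatongue.cortical_sheet import CouplingConfig
        from gammatongue.plasticity import simulate_learning

        cfg = CouplingConfig()
        K1 = gt.initial_coupling(small_sheet, cfg)
        traj = simulate_learning(
            small_simulator, K1, PsychometricParams(-1.0, 5.0), E=1.0,
            sessions=3, blocks=1, gamma=cfg.gamma,
        )
        for s, cm in traj.couplings.items():
            assert cm.K.min() >= 0 and cm.K.max() <= cfg.gamma + 1e-9
        assert set(traj.tongues) == {1, 2, 3}
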