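"""Learner internals: action selection, Kalman estimator, TD updates."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachlearn.learner import (
    DEFAULT_SEARCH_NOISE_SD,
    ExtendedStateEstimator,
    LearnerParams,
    LearnerState,
    estimator_step,
    kalman_gain,
    learner_trial,
    select_action,
    td_step,
)
from reachlearn.paradigm import Condition, RewardGeometry


def bayes_posterior_filter(observations, commands, a, q, sigma2, p0=0.0, P0=1.0):
    """Independent oracle: conjugate-Gaussian posterior recursion for the
    perturbation, written in information (precision-weighting) form."""
    mu, var = p0, P0
    out_mu, out_var = [], []
    for y, u in zip(observations, commands):
        mu, var = a * mu, a * a * var + q
        if y is not None:
            z = y - u  # direct noisy measurement of the perturbation
            prec = 1.0 / var + 1.0 / sigma2
            mu = (mu / var + z / sigma2) / prec
            var = 1.0 / prec
        out_mu.append(mu)
        out_var.append(var)
    return np.array(out_mu), np.array(out_var)


class TestSelectAction:
    @pytest.mark.parametrize(
        "p_hat,x_r,expected_u",
        [(0.0, 0.0, 0.0), (8.0, 0.0, -8.0), (0.0, -8.0, -8.0)],
    )
    def test_deterministic_policy(self, p_hat, x_r, expected_u):
        # same command from either memory: the central dissociation is in the
        # memories, not the behaviour
        params = LearnerParams(search_noise_sd=0.0)
        state = LearnerState(p_hat=p_hat, x_r=x_r)
        u, eta = select_action(state, params, 0.0, np.random.default_rng(0))
        assert u == expected_u and eta == 0.0

    def test_search_noise_returned_and_gaussian(self):
        params = LearnerParams(search_noise_sd=2.0)
        rng = np.random.default_rng(1)
        etas = [select_action(LearnerState(), params, 0.0, rng)[1] for _ in range(20_000)]
        assert np.std(etas) == pytest.approx(2.0, rel=0.05)


class TestKalmanGain:
    def test_reference_points(self):
        assert kalman_gain(1.0, 1.0) == 0.5
        assert kalman_gain(1.0, 0.0) == 1.0
        assert kalman_gain(1.0, 1e12) < 1e-11  # reward-only limit

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            kalman_gain(0.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        P=st.floats(1e-6, 1e3),
        s1=st.floats(1e-6, 1e3),
        s2=st.floats(1e-6, 1e3),
    )
    def test_gain_bounded_and_monotone_in_noise(self, P, s1, s2):
        k1, k2 = kalman_gain(P, s1), kalman_gain(P, s2)
        assert 0 <= k1 <= 1
        if s1 < s2:
            assert k1 > k2


class TestEstimatorStep:
    def test_full_credit_single_step(self):
        params = LearnerParams(retention=1.0, process_noise_var=0.0,
                               observation_noise_var=0.0)
        state = LearnerState(p_hat=0.0, est_uncertainty=1.0)
        new = estimator_step(state, params, 0.0, 8.0)
        assert new.p_hat == pytest.approx(8.0)

    def test_no_observation_leaves_estimate_at_initial_value(self):
        params = LearnerParams()
        state = LearnerState(p_hat=0.0)
        for _ in range(500):
            state = estimator_step(state, params, -5.0, None)
        assert state.p_hat == 0.0  # exactly: no sensory remapping without vision

    def test_steady_state_tracks_constant_discrepancy(self):
        # constant y - u = 8 with retention 1: Bayes-optimal filter converges
        params = LearnerParams(retention=1.0, process_noise_var=0.01,
                               observation_noise_var=1.0)
        state = LearnerState()
        for _ in range(400):
            state = estimator_step(state, params, 0.0, 8.0)
        mu, _ = bayes_posterior_filter([8.0] * 400, [0.0] * 400, 1.0, 0.01, 1.0)
        assert state.p_hat == pytest.approx(mu[-1], abs=1e-9)
        assert abs(state.p_hat - 8.0) < 0.5

    def test_matches_bayes_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = rng.uniform(0.8, 1.0)
            q = rng.uniform(1e-3, 0.5)
            sigma2 = rng.uniform(0.1, 50.0)
            n = 60
            us = rng.normal(0, 3, n)
            ys = us + rng.normal(0, 2, n)
            obs = [None if rng.random() < 0.2 else float(y) for y in ys]
            params = LearnerParams(retention=a, process_noise_var=q,
                                   observation_noise_var=sigma2)
            state = LearnerState()
            got_mu, got_var = [], []
            for u, y in zip(us, obs):
                state = estimator_step(state, params, float(u), y)
                got_mu.append(state.p_hat)
                got_var.append(state.est_uncertainty)
            mu, var = bayes_posterior_filter(obs, us, a, q, sigma2)
            np.testing.assert_allclose(got_mu, mu, atol=1e-9)
            np.testing.assert_allclose(got_var, var, atol=1e-9)

    def test_matrix_backend_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        params = LearnerParams(retention=0.97, process_noise_var=0.05,
                               observation_noise_var=2.0)
        scalar = LearnerState()
        matrix = ExtendedStateEstimator(params)
        for _ in range(200):
            u = float(rng.normal(0, 3))
            y = None if rng.random() < 0.3 else float(u + rng.normal(2, 1))
            scalar = estimator_step(scalar, params, u, y)
            matrix.step(u, y)
            assert matrix.p_hat == pytest.approx(scalar.p_hat, abs=1e-9)
            assert matrix.est_uncertainty == pytest.approx(
                scalar.est_uncertainty, abs=1e-9
            )

    def test_nonfinite_observation_rejected(self):
        with pytest.raises(ValueError):
            estimator_step(LearnerState(), LearnerParams(), 0.0, float("nan"))


class TestTDStep:
    def test_zero_prediction_error_is_inert(self):
        # gamma=0 and reward exactly equal to the critic's value
        params = LearnerParams(discount=0.0)
        state = LearnerState(value=0.5, x_r=1.0, last_search_noise=1.0)
        new = td_step(state, params, 0.5)
        assert new.x_r == state.x_r and new.value == state.value

    def test_reinforces_explored_direction(self):
        params = LearnerParams(discount=0.0, actor_lr=0.1, critic_lr=0.1)
        state = LearnerState(value=0.0, last_search_noise=1.0)
        new = td_step(state, params, 1.0)
        assert new.x_r == pytest.approx(0.1)
        assert new.value == pytest.approx(0.1)

    def test_hill_climbs_into_reachable_reward_zone(self):
        # stochastic hill-climbing: zone [-6, 0] with its boundary at the
        # naive start point; the policy must settle inside it
        params = LearnerParams(search_noise_sd=1.0, actor_lr=0.15, critic_lr=0.15,
                               discount=0.0, motor_noise_sd=0.0)
        rng = np.random.default_rng(0)
        state = LearnerState()
        us = []
        for _ in range(2000):
            u, eta = select_action(state, params, 0.0, rng)
            r = 1.0 if -6.0 <= u <= 0.0 else 0.0
            state = replace(state, last_search_noise=eta)
            state = td_step(state, params, r)
            us.append(u)
        mean_final = np.mean(us[-200:])
        assert -6.0 < mean_final < -0.5


class TestLearnerTrial:
    def test_noiseless_trial_is_quiet(self):
        cond = Condition("ERR", observation_noise_sd=0.0)
        params = LearnerParams(motor_noise_sd=0.0, search_noise_sd=0.0,
                               observation_noise_var=1.0)
        state, rec = learner_trial(
            LearnerState(), params, cond, RewardGeometry(), 0.0,
            np.random.default_rng(0),
        )
        assert rec.hand_angle == 0.0 and rec.rewarded == 1
        assert state.p_hat == 0.0 and state.x_r == 0.0

    def test_rwd_trial_never_updates_perturbation_estimate(self):
        cond = Condition.from_label("RWD")
        params = LearnerParams.for_condition(cond)
        state = LearnerState()
        rng = np.random.default_rng(3)
        for k in range(50):
            state, rec = learner_trial(state, params, cond, RewardGeometry(), 8.0, rng)
            assert rec.observed_cursor is None
            assert state.p_hat == 0.0

    def test_err_noiseless_single_step_full_absorption(self):
        cond = Condition("ERR", observation_noise_sd=0.0)
        params = LearnerParams(motor_noise_sd=0.0, search_noise_sd=0.0,
                               observation_noise_var=0.0)
        state, _ = learner_trial(
            LearnerState(), params, cond, RewardGeometry(), 8.0,
            np.random.default_rng(0),
        )
        assert state.p_hat == pytest.approx(8.0)

    def test_condition_search_noise_defaults_ordered(self):
        sds = [DEFAULT_SEARCH_NOISE_SD[c] for c in ("ERR", "EPE", "RWD")]
        assert sds[0] < sds[1] < sds[2]
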