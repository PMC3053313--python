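"""Dual-memory model fitting: filter correctness, recovery, diagnostics."""

import numpy as np
import pytest

from reachlearn.fitting import (
    DualMemoryModel,
    FilterParams,
    decompose,
    fit_subject,
    forward_filter,
)
from reachlearn.learner import LearnerParams
from reachlearn.paradigm import Condition, build_schedule
from reachlearn.simulate import run_condition


@pytest.fixture(scope="module")
def exp1_sched():
    return build_schedule("EXP1")


class TestForwardFilter:
    def test_inert_model_leaves_everything_in_residual(self, err_runs):
        trials = err_runs[0].trials
        params = FilterParams(actor_lr=0.0, critic_lr=0.0,
                              observation_noise_var=1e12, process_noise_var=1e-12,
                              initial_uncertainty=1e-12)
        x_p, x_r, eta = forward_filter(trials, params, "ERR")
        np.testing.assert_allclose(x_p, 0.0, atol=1e-6)
        np.testing.assert_allclose(x_r, 0.0, atol=1e-12)
        np.testing.assert_allclose(eta, trials["reach_deg"], atol=1e-6)

    def test_rwd_gain_forced_zero_regardless_of_variance(self, rwd_runs):
        trials = rwd_runs[0].trials
        params = FilterParams(observation_noise_var=1e-9, actor_lr=0.15,
                              critic_lr=0.15)
        x_p, x_r, eta = forward_filter(trials, params, "RWD")
        np.testing.assert_array_equal(x_p, 0.0)

    def test_self_consistency_with_recorded_noises(self, exp1_sched):
        # filtering a series generated with zero motor and perceptual noise
        # but nonzero search noise must return the generating trajectories
        cond = Condition("ERR", observation_noise_sd=0.0)
        gen = LearnerParams.for_condition(
            cond, motor_noise_sd=0.0, observation_noise_var=1.0, search_noise_sd=0.5
        )
        res = run_condition(gen, exp1_sched, cond, seed=3)
        params = FilterParams(
            observation_noise_var=gen.observation_noise_var,
            actor_lr=gen.actor_lr, critic_lr=gen.critic_lr,
            process_noise_var=gen.process_noise_var,
            retention=gen.retention, discount=gen.discount,
        )
        x_p, x_r, eta = forward_filter(res.trials, params, "ERR")
        t = res.trials
        np.testing.assert_allclose(eta, t["search_deg"], atol=1e-9)
        np.testing.assert_allclose(x_p, -t["p_hat_pre_deg"], atol=1e-9)
        np.testing.assert_allclose(x_r, t["x_r_pre_deg"], atol=1e-9)

    def test_missing_columns_rejected(self, err_runs):
        bad = err_runs[0].trials.drop(columns=["rewarded"])
        with pytest.raises(ValueError):
            forward_filter(bad, FilterParams(), "ERR")

    def test_short_series_rejected(self, err_runs):
        with pytest.raises(ValueError):
            DualMemoryModel.from_dataframe(err_runs[0].trials.head(30), "ERR")


class TestFit:
    def test_self_fit_noiseless_reaches_zero_sse(self, exp1_sched):
        cond = Condition("ERR", observation_noise_sd=0.0)
        gen = LearnerParams.for_condition(
            cond, motor_noise_sd=0.0, search_noise_sd=0.0, observation_noise_var=1.0
        )
        res = run_condition(gen, exp1_sched, cond, seed=0)
        fit = fit_subject(res.trials, "ERR", n_starts=10, seed=1)
        assert fit.converged
        assert fit.sse < 1e-6

    def test_objective_identity(self, err_runs):
        fit = fit_subject(err_runs[0].trials, "ERR", n_starts=4, seed=0)
        assert fit.sse == pytest.approx(float(np.sum(fit.eta_by_trial**2)), abs=1e-9)

    def test_fit_deterministic_given_seed(self, rwd_runs):
        a = fit_subject(rwd_runs[0].trials, "RWD", n_starts=4, seed=9)
        b = fit_subject(rwd_runs[0].trials, "RWD", n_starts=4, seed=9)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_err_subject_recovers_all_sensory_split(self, exp1_sched):
        # generated with negligible reward learning: the fit must attribute
        # the adaptation to the sensory memory
        cond = Condition.from_label("ERR")
        gen = LearnerParams.for_condition(cond, actor_lr=0.01)
        xps, xrs, adapt = [], [], []
        for seed in range(3):
            res = run_condition(gen, exp1_sched, cond, seed=seed)
            fit = fit_subject(res.trials, "ERR", n_starts=8, seed=seed)
            x_p, x_r, _ = fit.decompose(80)
            xps.append(x_p)
            xrs.append(x_r)
            adapt.append(res.summary.adaptation)
        assert abs(abs(np.mean(xps)) - np.mean(adapt)) < 1.0
        assert abs(np.mean(xrs)) < 1.0

    def test_rwd_subject_recovers_all_reward_split(self, rwd_runs):
        xps, xrs, adapt = [], [], []
        for res in rwd_runs[:3]:
            fit = fit_subject(res.trials, "RWD", n_starts=8, seed=0)
            x_p, x_r, _ = fit.decompose(80)
            xps.append(x_p)
            xrs.append(x_r)
            adapt.append(res.summary.adaptation)
        assert np.all(np.asarray(xps) == 0.0)
        assert abs(abs(np.mean(xrs)) - np.mean(adapt)) < 1.5

    def test_rwd_actor_rate_recovered(self, rwd_runs):
        # the actor learning rate is identifiable from a reward-only series
        rates = []
        for res in rwd_runs[:6]:
            fit = fit_subject(res.trials, "RWD", n_starts=8, seed=0)
            rates.append(fit.params["actor_lr"])
        true = LearnerParams.for_condition(Condition.from_label("RWD")).actor_lr
        assert abs(np.median(rates) - true) / true < 0.5

    def test_split_rates_mapping_available(self, epe_runs):
        fit = fit_subject(
            epe_runs[0].trials, "EPE", n_starts=4, seed=0,
            param_mapping="split_rates",
        )
        assert set(fit.params) == {"observation_noise_var", "critic_lr", "actor_lr"}
        assert fit.converged

    def test_summary_is_printable(self, rwd_runs):
        fit = fit_subject(rwd_runs[0].trials, "RWD", n_starts=4, seed=0)
        text = fit.summary()
        assert "RWD" in text and "SSE" in text and "actor_lr" in text


class TestDecompose:
    def test_requires_converged_fit(self, rwd_runs):
        fit = fit_subject(rwd_runs[0].trials, "RWD", n_starts=4, seed=0)
        fit.converged = False
        with pytest.raises(ValueError):
            decompose(fit)

    def test_window_exceeding_series_rejected(self, rwd_runs):
        fit = fit_subject(rwd_runs[0].trials, "RWD", n_starts=4, seed=0)
        with pytest.raises(ValueError):
            fit.decompose(window=10_000)

    def test_search_noise_variance_matches_generating_noise(self, rwd_runs):
        # residual variance ~ search variance + motor variance
        fit = fit_subject(rwd_runs[0].trials, "RWD", n_starts=8, seed=0)
        _, _, var = fit.decompose(80)
        gen = LearnerParams.for_condition(Condition.from_label("RWD"))
        expected = gen.search_noise_sd**2 + gen.motor_noise_sd**2
        assert var == pytest.approx(expected, rel=0.35)
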