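"""The optimal learner: Kalman perturbation estimator + actor-critic policy.

Two memories jointly compensate a visuomotor rotation:

* a *state estimator* tracking the perturbation ``p`` with a scalar Kalman
  filter driven by the sensory prediction error ``y - (u + p_hat)``;
* an *action selector* holding a reward-driven offset ``x_r`` updated by a
  temporal-difference (TD) reward prediction error along the executed
  exploration (search) noise.

Per trial the command is ``u = (target - p_hat) + x_r + eta`` with search
noise ``eta``.  The estimator absorbs the rotation only when an observation
is available; with the visual channel absent (RWD) the perturbation estimate
never moves, yet the actor can still steer the hand into the reward zone —
the dissociation between sensory remapping and reward-based adaptation.

The learner's estimate of its own hand position is the forward-model
prediction ``h_hat = u + p_hat``: as the estimator absorbs the rotation,
``h_hat`` migrates toward the cursor and away from the true hand, which is
the modelled sensory remapping (localization illusion).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .paradigm import (
    Condition,
    RewardGeometry,
    TrialRecord,
    cursor_from_hand,
    is_hit,
    observe_cursor,
    reward,
)

__all__ = [
    "LearnerParams",
    "LearnerState",
    "DEFAULT_SEARCH_NOISE_SD",
    "select_action",
    "kalman_gain",
    "estimator_step",
    "td_step",
    "learner_trial",
    "ExtendedStateEstimator",
]

#: Default active-search-noise standard deviation (degrees) per condition.
#: Exploration grows as the sensory channel degrades (fitted search-noise
#: variance ordering ERR < EPE < RWD).
DEFAULT_SEARCH_NOISE_SD = {"ERR": 0.5, "EPE": 1.0, "RWD": 1.5}


@dataclass(frozen=True)
class LearnerParams:
    """All constants of the learner.

    Parameters
    ----------
    retention : float
        Trial-to-trial retention of the perturbation prior, A in (0, 1].
    process_noise_var : float
        Variance of the perturbation's random walk, deg^2.
    observation_noise_var : float
        Perceptual-noise variance assumed by the estimator, deg^2.
    motor_noise_sd : float
        Passive execution noise on the hand, degrees.
    search_noise_sd : float
        Active exploration noise added to the command, degrees.
    actor_lr, critic_lr : float
        Learning rates of the policy offset and the value estimate, in [0, 1].
    discount : float
        TD discount factor gamma in [0, 1).
    motor_cost_scale : float
        Quadratic motor-cost coefficient lambda (reward = hit - lambda u^2).
    """

    retention: float = 0.99
    process_noise_var: float = 0.01
    observation_noise_var: float = 1.0
    motor_noise_sd: float = 1.0
    search_noise_sd: float = 0.5
    actor_lr: float = 0.15
    critic_lr: float = 0.15
    discount: float = 0.9
    motor_cost_scale: float = 0.0

    def __post_init__(self):
        if not (0 < self.retention <= 1):
            raise ValueError("retention must be in (0, 1]")
        for name in ("process_noise_var", "observation_noise_var",
                     "motor_noise_sd", "search_noise_sd", "motor_cost_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("actor_lr", "critic_lr"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 <= self.discount < 1):
            raise ValueError("discount must be in [0, 1)")

    @classmethod
    def for_condition(cls, condition: Condition, **overrides) -> "LearnerParams":
        """Defaults matched to a feedback condition.

        The estimator's assumed observation-noise variance equals the
        condition's actual perceptual-noise variance; search noise follows
        the per-condition default unless overridden.  For RWD the
        observation variance is irrelevant (the gain is forced to zero by
        the absent observation).
        """
        kwargs = {}
        if condition.has_observation:
            kwargs["observation_noise_var"] = float(condition.observation_noise_sd) ** 2
        kwargs["search_noise_sd"] = DEFAULT_SEARCH_NOISE_SD[condition.label]
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class LearnerState:
    """Evolving quantities: perturbation estimate and its uncertainty,
    reward-driven policy offset, critic value, and bookkeeping."""

    p_hat: float = 0.0
    est_uncertainty: float = 1.0
    x_r: float = 0.0
    value: float = 0.0
    last_search_noise: float = 0.0
    h_hat: float = 0.0

    def __post_init__(self):
        if self.est_uncertainty < 0:
            raise ValueError("est_uncertainty must be >= 0")


def select_action(
    state: LearnerState,
    params: LearnerParams,
    target: float,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """Draw the motor command for one trial.

    Returns ``(command, eta)`` with
    ``command = (target - p_hat) + x_r + eta`` and
    ``eta ~ N(0, search_noise_sd^2)``.  With the target at 0 this is the
    two-memory decomposition ``u = x_p + x_r + eta`` with ``x_p = -p_hat``.
    """
    if params.search_noise_sd > 0:
        eta = float(rng.normal(0.0, params.search_noise_sd))
    else:
        eta = 0.0
    u = (target - state.p_hat) + state.x_r + eta
    return u, eta


def kalman_gain(est_uncertainty_prior: float, observation_noise_var: float) -> float:
    """K = P- / (P- + sigma_y^2); in [0, 1], decreasing in the noise variance."""
    if est_uncertainty_prior < 0 or observation_noise_var < 0:
        raise ValueError("uncertainties must be >= 0")
    denom = est_uncertainty_prior + observation_noise_var
    if denom == 0:
        raise ValueError("prior uncertainty and observation noise cannot both be zero")
    return est_uncertainty_prior / denom


def estimator_step(
    state: LearnerState,
    params: LearnerParams,
    motor_command: float,
    observed_cursor: Optional[float],
) -> LearnerState:
    """One trial of the forward-model / Kalman-filter recursion.

    Time update: ``p- = A p_hat``, ``P- = A^2 P + q``.  With an observation,
    the predicted cursor is ``u + p-`` and the sensory prediction error
    corrects the estimate with gain K; without one the gain is zero and the
    prior is carried forward unchanged.
    """
    if observed_cursor is not None and not np.isfinite(observed_cursor):
        raise ValueError("observed_cursor must be finite")
    a = params.retention
    p_prior = a * state.p_hat
    P_prior = a * a * state.est_uncertainty + params.process_noise_var
    if observed_cursor is None:
        p_post, P_post = p_prior, P_prior
    else:
        y_pred = motor_command + p_prior
        K = kalman_gain(P_prior, params.observation_noise_var)
        p_post = p_prior + K * (observed_cursor - y_pred)
        P_post = (1.0 - K) * P_prior
    # forward-model hand estimate: efference copy plus credited perturbation
    h_hat = motor_command + p_post
    return replace(state, p_hat=p_post, est_uncertainty=P_post, h_hat=h_hat)


def td_step(
    state: LearnerState, params: LearnerParams, reward_received: float
) -> LearnerState:
    """One temporal-difference update of critic and actor.

    One reach is one TD step; the successor value is the current critic
    value, so ``delta = r + gamma*v - v``.  The critic moves by
    ``critic_lr * delta`` and the actor offset by
    ``actor_lr * delta * eta`` along the executed search noise.
    """
    delta = reward_received + params.discount * state.value - state.value
    v = state.value + params.critic_lr * delta
    x_r = state.x_r + params.actor_lr * delta * state.last_search_noise
    return replace(state, value=v, x_r=x_r)


def learner_trial(
    state: LearnerState,
    params: LearnerParams,
    condition: Condition,
    geometry: RewardGeometry,
    rotation: float,
    rng: np.random.Generator,
    *,
    target: float = 0.0,
    trial_index: int = 0,
    phase: str = "",
) -> Tuple[LearnerState, TrialRecord]:
    """Run one full trial: act, execute, observe, evaluate, learn."""
    p_hat_pre, x_r_pre = state.p_hat, state.x_r
    u, eta = select_action(state, params, target, rng)
    if params.motor_noise_sd > 0:
        motor_noise = float(rng.normal(0.0, params.motor_noise_sd))
    else:
        motor_noise = 0.0
    hand = u + motor_noise
    cursor = cursor_from_hand(hand, rotation)
    observed = observe_cursor(cursor, condition, rng)
    hit = is_hit(cursor, geometry)
    r = reward(cursor, u, geometry)
    state = replace(state, last_search_noise=eta)
    state = estimator_step(state, params, u, observed)
    state = td_step(state, params, r)
    record = TrialRecord(
        trial_index=trial_index,
        phase=phase,
        target_direction=target,
        imposed_rotation=rotation,
        motor_command=u,
        hand_angle=hand,
        cursor_angle=cursor,
        observed_cursor=observed,
        rewarded=int(hit),
        cursor_shown=condition.has_observation,
        search_noise=eta,
        motor_noise=motor_noise,
        p_hat_pre=p_hat_pre,
        x_r_pre=x_r_pre,
        p_hat_post=state.p_hat,
        x_r_post=state.x_r,
        h_hat=state.h_hat,
        value_post=state.value,
    )
    return state, record


class ExtendedStateEstimator:
    """Matrix-form backend of the estimator over the extended state [h, p, t].

    The hand component is reset to the efference copy each trial (no carried
    uncertainty), the perturbation follows the retention/process-noise random
    walk, and the target is a known constant; the observation is
    ``y = h + p + noise``.  Its perturbation posterior agrees with the scalar
    reduction to floating-point precision.
    """

    def __init__(self, params: LearnerParams, target: float = 0.0,
                 p0: float = 0.0, P0: float = 1.0):
        self.params = params
        self.x = np.array([0.0, p0, target])
        self.P = np.diag([0.0, P0, 0.0])
        a = params.retention
        self.A = np.diag([0.0, a, 1.0])
        self.B = np.array([1.0, 0.0, 0.0])
        self.Q = np.diag([0.0, params.process_noise_var, 0.0])
        self.H = np.array([1.0, 1.0, 0.0])

    @property
    def p_hat(self) -> float:
        return float(self.x[1])

    @property
    def est_uncertainty(self) -> float:
        return float(self.P[1, 1])

    def step(self, motor_command: float, observed_cursor: Optional[float]) -> None:
        x_prior = self.A @ self.x + self.B * motor_command
        P_prior = self.A @ self.P @ self.A.T + self.Q
        if observed_cursor is None:
            self.x, self.P = x_prior, P_prior
            return
        S = float(self.H @ P_prior @ self.H) + self.params.observation_noise_var
        if S == 0:
            raise ValueError("degenerate observation: zero innovation variance")
        K = (P_prior @ self.H) / S
        innovation = observed_cursor - float(self.H @ x_prior)
        self.x = x_prior + K * innovation
        self.P = (np.eye(3) - np.outer(K, self.H)) @ P_prior
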