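"""Run the learner through a full paradigm and summarize the outcome.

The summaries mirror the quantities used to characterize behaviour:
adaptation amount (change in mean reach from baseline to the final
plateau), reach variability over the final trials, fraction of rewarded
trials in the adaptation phase, terminal sensory remapping (mean
perturbation estimate), and the modelled localization illusion
(estimated minus actual hand position).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .learner import LearnerParams, LearnerState, learner_trial
from .paradigm import (
    Condition,
    PerturbationSchedule,
    RewardGeometry,
    TrialRecord,
    build_schedule,
)

__all__ = [
    "SummaryStats",
    "SimulationResult",
    "run_condition",
    "records_to_frame",
    "summarize",
    "uncertainty_sweep",
]

TRIAL_COLUMNS = [
    "trial", "phase", "target_deg", "rotation_deg", "command_deg", "reach_deg",
    "cursor_deg", "observed_deg", "rewarded", "cursor_shown", "search_deg",
    "motor_noise_deg", "p_hat_pre_deg", "x_r_pre_deg", "p_hat_deg", "x_r_deg",
    "h_hat_deg", "value",
]


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Stack per-trial records into the canonical trial table."""
    return pd.DataFrame(
        {
            "trial": [r.trial_index for r in records],
            "phase": [r.phase for r in records],
            "target_deg": [r.target_direction for r in records],
            "rotation_deg": [r.imposed_rotation for r in records],
            "command_deg": [r.motor_command for r in records],
            "reach_deg": [r.hand_angle for r in records],
            "cursor_deg": [r.cursor_angle for r in records],
            "observed_deg": [
                np.nan if r.observed_cursor is None else r.observed_cursor
                for r in records
            ],
            "rewarded": [r.rewarded for r in records],
            "cursor_shown": [r.cursor_shown for r in records],
            "search_deg": [r.search_noise for r in records],
            "motor_noise_deg": [r.motor_noise for r in records],
            "p_hat_pre_deg": [r.p_hat_pre for r in records],
            "x_r_pre_deg": [r.x_r_pre for r in records],
            "p_hat_deg": [r.p_hat_post for r in records],
            "x_r_deg": [r.x_r_post for r in records],
            "h_hat_deg": [r.h_hat for r in records],
            "value": [r.value_post for r in records],
        }
    )


@dataclass(frozen=True)
class SummaryStats:
    """Behavioural summary of one simulated (or loaded) session."""

    adaptation: float
    reach_sd_final100: float
    reward_fraction: float
    remapping: float
    illusion_index: float
    terminal_p_hat: float
    terminal_x_r: float
    final_window: int

    def __post_init__(self):
        if not (0 <= self.reward_fraction <= 1):
            raise ValueError("reward_fraction must lie in [0, 1]")
        if self.reach_sd_final100 < 0:
            raise ValueError("reach_sd_final100 must be >= 0")


@dataclass
class SimulationResult:
    """Full trial table plus per-trial memory trajectories and the summary."""

    trials: pd.DataFrame
    p_hat_by_trial: np.ndarray
    h_hat_by_trial: np.ndarray
    summary: SummaryStats
    condition: Condition
    params: LearnerParams
    schedule: PerturbationSchedule
    geometry: RewardGeometry
    seed: Optional[int]

    def __post_init__(self):
        n = len(self.schedule)
        if not (len(self.trials) == len(self.p_hat_by_trial) == len(self.h_hat_by_trial) == n):
            raise ValueError("trial table and trajectories must match schedule length")


def summarize(
    trials: pd.DataFrame,
    schedule: PerturbationSchedule,
    p_hat_by_trial: np.ndarray,
    h_hat_by_trial: np.ndarray,
    final_window: int = 100,
) -> SummaryStats:
    """Compute the behavioural summary from a trial table.

    ``adaptation`` is the absolute change in mean reach from the baseline
    block to the final ``final_window`` trials of the plateau.
    ``reach_sd_final100`` uses the population-SD convention (ddof=0).
    ``reward_fraction`` is computed over adaptation-phase trials only.
    """
    n = len(trials)
    if final_window > n or final_window < 1:
        raise ValueError("final_window must be in [1, n_trials]")
    reach = trials["reach_deg"].to_numpy(dtype=float)
    baseline = schedule.phase_labels == "baseline"
    adapt = schedule.adaptation_mask()
    baseline_mean = reach[baseline].mean() if baseline.any() else 0.0
    final = slice(n - final_window, n)
    adaptation = abs(reach[final].mean() - baseline_mean)
    reach_sd = float(np.std(reach[final], ddof=0))
    rewarded = trials["rewarded"].to_numpy(dtype=float)
    reward_fraction = float(rewarded[adapt].mean()) if adapt.any() else float(rewarded.mean())
    remapping = float(np.mean(p_hat_by_trial[final]))
    illusion = float(np.mean(h_hat_by_trial[final] - reach[final]))
    return SummaryStats(
        adaptation=float(adaptation),
        reach_sd_final100=reach_sd,
        reward_fraction=reward_fraction,
        remapping=remapping,
        illusion_index=illusion,
        terminal_p_hat=float(p_hat_by_trial[-1]),
        terminal_x_r=float(trials["x_r_deg"].iloc[-1]),
        final_window=final_window,
    )


def run_condition(
    params: LearnerParams,
    schedule: PerturbationSchedule,
    condition: Condition,
    geometry: Optional[RewardGeometry] = None,
    seed: Optional[int] = 0,
    final_window: int = 100,
) -> SimulationResult:
    """Simulate the learner through a full perturbation schedule.

    Deterministic given ``seed``; the trained target is at 0 degrees
    throughout.
    """
    geometry = geometry or RewardGeometry()
    rng = np.random.default_rng(seed)
    state = LearnerState()
    records = []
    for k in range(len(schedule)):
        state, rec = learner_trial(
            state,
            params,
            condition,
            geometry,
            float(schedule.rotation_by_trial[k]),
            rng,
            target=geometry.target_direction,
            trial_index=k,
            phase=str(schedule.phase_labels[k]),
        )
        records.append(rec)
    trials = records_to_frame(records)
    p_hat = trials["p_hat_deg"].to_numpy(dtype=float)
    h_hat = trials["h_hat_deg"].to_numpy(dtype=float)
    stats = summarize(trials, schedule, p_hat, h_hat, final_window=final_window)
    return SimulationResult(
        trials=trials,
        p_hat_by_trial=p_hat,
        h_hat_by_trial=h_hat,
        summary=stats,
        condition=condition,
        params=params,
        schedule=schedule,
        geometry=geometry,
        seed=seed,
    )


def uncertainty_sweep(
    params_base: LearnerParams,
    sigma_grid: Sequence[float],
    n_seeds: int = 20,
    schedule: Optional[PerturbationSchedule] = None,
    seeds: Optional[Sequence[int]] = None,
    geometry: Optional[RewardGeometry] = None,
) -> pd.DataFrame:
    """Sweep the perceptual-noise variance and aggregate terminal behaviour.

    Each cell simulates a continuous-cursor learner whose actual and assumed
    observation-noise variance both equal the grid value; remapping should
    fall with the variance while adaptation stays flat (the reward channel
    absorbs what the sensory channel loses).
    """
    if len(sigma_grid) == 0:
        raise ValueError("sigma_grid must be non-empty")
    schedule = schedule or build_schedule("EXP1")
    if seeds is None:
        seeds = list(range(n_seeds))
    rows = []
    for sigma2 in sorted(float(s) for s in sigma_grid):
        cond = Condition("ERR", observation_noise_sd=float(np.sqrt(sigma2)))
        params = LearnerParams(
            **{
                **params_base.__dict__,
                "observation_noise_var": float(sigma2),
            }
        )
        cell = [
            run_condition(params, schedule, cond, geometry=geometry, seed=s).summary
            for s in seeds
        ]
        rows.append(
            {
                "sigma_y2": sigma2,
                "remapping": float(np.mean([c.remapping for c in cell])),
                "adaptation": float(np.mean([c.adaptation for c in cell])),
                "reward_fraction": float(np.mean([c.reward_fraction for c in cell])),
                "reach_sd_final100": float(np.mean([c.reach_sd_final100 for c in cell])),
                "n_seeds": len(list(seeds)),
            }
        )
    return pd.DataFrame(rows)
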