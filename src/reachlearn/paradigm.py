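"""Task paradigms for visuomotor rotation adaptation with graded feedback.

Encodes the three feedback regimes used to dissociate error-based from
reward-based motor learning:

* ``ERR`` — the cursor is visible throughout the reach (rich sensory
  prediction error, low perceptual uncertainty).
* ``EPE`` — the cursor is flashed only at the movement endpoint
  (sensory prediction error with elevated perceptual uncertainty).
* ``RWD`` — no cursor at all; the only feedback is the binary success
  signal (reward prediction error only).

All angles are in degrees with clockwise positive.  A trial's generative
chain is

    hand  = command + motor noise
    cursor = hand + rotation
    observation = cursor + perceptual noise   (absent in RWD)
    reward = hit(cursor) - lambda * command**2

where ``hit`` is 1 when the cursor crosses within the target's angular
half-width and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "Condition",
    "PerturbationSchedule",
    "RewardGeometry",
    "TrialRecord",
    "build_schedule",
    "cursor_from_hand",
    "observe_cursor",
    "is_hit",
    "reward",
    "CONDITION_LABELS",
    "EXPERIMENT_IDS",
    "DEFAULT_OBSERVATION_NOISE_SD",
]

CONDITION_LABELS = ("ERR", "EPE", "RWD")
EXPERIMENT_IDS = ("EXP1", "EXP2", "EXP3")

#: Default perceptual-noise standard deviation (degrees) per condition.
#: ERR: small (continuous high-quality vision).  EPE: endpoint flash only;
#: variance 8x the ERR default.  RWD: the visual channel is absent, which is
#: represented as None (estimator gain forced to zero), not as a large number.
DEFAULT_OBSERVATION_NOISE_SD = {"ERR": 1.0, "EPE": float(np.sqrt(8.0)), "RWD": None}

_VISIBILITY = {"ERR": "continuous", "EPE": "endpoint_only", "RWD": "none"}


@dataclass(frozen=True)
class Condition:
    """A feedback regime: cursor visibility plus perceptual-noise magnitude.

    Parameters
    ----------
    label : {"ERR", "EPE", "RWD"}
    cursor_visibility : {"continuous", "endpoint_only", "none"}
        Fixed by the label; kept explicit for serialization.
    observation_noise_sd : float or None
        Standard deviation of the perceptual noise on the observed cursor,
        degrees.  ``None`` means the observation channel is absent (RWD).
    """

    label: str
    cursor_visibility: str = ""
    observation_noise_sd: Optional[float] = None

    def __post_init__(self):
        if self.label not in CONDITION_LABELS:
            raise ValueError(f"unknown condition label {self.label!r}")
        expected = _VISIBILITY[self.label]
        if not self.cursor_visibility:
            object.__setattr__(self, "cursor_visibility", expected)
        elif self.cursor_visibility != expected:
            raise ValueError(
                f"{self.label} requires cursor_visibility={expected!r}, "
                f"got {self.cursor_visibility!r}"
            )
        if self.label == "RWD":
            if self.observation_noise_sd is not None:
                raise ValueError("RWD has no observation channel; leave noise as None")
        else:
            if self.observation_noise_sd is None:
                object.__setattr__(
                    self,
                    "observation_noise_sd",
                    DEFAULT_OBSERVATION_NOISE_SD[self.label],
                )
            if not np.isfinite(self.observation_noise_sd) or self.observation_noise_sd < 0:
                raise ValueError("observation_noise_sd must be finite and >= 0")

    @property
    def has_observation(self) -> bool:
        return self.label != "RWD"

    @classmethod
    def from_label(cls, label: str, observation_noise_sd: Optional[float] = None) -> "Condition":
        return cls(label=label, observation_noise_sd=observation_noise_sd)


@dataclass(frozen=True)
class RewardGeometry:
    """Reward-zone geometry and motor-cost scaling.

    The target subtends ``target_width`` degrees (6 by default); a reach is
    rewarded when the cursor crosses within ``target_width / 2`` of the
    target direction, boundary inclusive.  ``motor_cost_scale`` is the
    quadratic motor-cost coefficient; the experimental feedback itself is
    binary, so it defaults to 0 and the scalar reward equals the hit flag.
    """

    target_direction: float = 0.0
    target_width: float = 6.0
    motor_cost_scale: float = 0.0
    target_distance_cm: float = 10.0

    def __post_init__(self):
        if self.target_width <= 0:
            raise ValueError("target_width must be positive")
        if self.motor_cost_scale < 0:
            raise ValueError("motor_cost_scale must be >= 0")

    @property
    def half_width(self) -> float:
        return self.target_width / 2.0


@dataclass(frozen=True)
class PerturbationSchedule:
    """Per-trial imposed rotation sequence with block/phase annotations."""

    experiment_id: str
    rotation_by_trial: np.ndarray
    phase_labels: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation_by_trial, dtype=float)
        phases = np.asarray(self.phase_labels, dtype=object)
        if rot.shape != phases.shape:
            raise ValueError("rotation and phase arrays must have equal length")
        if np.max(np.abs(rot)) > 8:
            raise ValueError("rotations must lie in [-8, 8] degrees")
        object.__setattr__(self, "rotation_by_trial", rot)
        object.__setattr__(self, "phase_labels", phases)

    def __len__(self) -> int:
        return len(self.rotation_by_trial)

    @property
    def n_baseline(self) -> int:
        return int(np.sum(self.phase_labels == "baseline"))

    def adaptation_mask(self) -> np.ndarray:
        """Boolean mask of trials in the adaptation phase (everything after
        the zero-rotation baseline block)."""
        return self.phase_labels != "baseline"

    def plateau_mask(self) -> np.ndarray:
        """Trials at the full plateau rotation (hold + extra hold blocks)."""
        return np.isin(self.phase_labels, ("hold", "extra_hold"))


# Extra plateau trials appended after the mid-session break:
# EXP1: 96 trials; EXP2: three 48-trial blocks; EXP3: two 48-trial blocks.
_EXTRA_PLATEAU = {"EXP1": 96, "EXP2": 144, "EXP3": 96}
_PLATEAU_SIGN = {"EXP1": +1, "EXP2": -1, "EXP3": -1}


def build_schedule(experiment_id: str) -> PerturbationSchedule:
    """Build the full per-trial rotation schedule for one experiment.

    Every schedule starts with 40 zero-rotation baseline trials, then ramps
    the rotation magnitude by 1 degree every 40 trials up to 8, holds the
    8-degree plateau for 80 trials, and appends the experiment's extra
    plateau trials.  EXP1 ramps clockwise (+), EXP2/EXP3 counter-clockwise (-).
    """
    if experiment_id not in EXPERIMENT_IDS:
        raise ValueError(f"unknown experiment_id {experiment_id!r}")
    sign = _PLATEAU_SIGN[experiment_id]
    rotations: list[float] = [0.0] * 40
    phases: list[str] = ["baseline"] * 40
    for magnitude in range(1, 8):
        rotations += [sign * float(magnitude)] * 40
        phases += ["ramp"] * 40
    rotations += [sign * 8.0] * 80
    phases += ["hold"] * 80
    n_extra = _EXTRA_PLATEAU[experiment_id]
    rotations += [sign * 8.0] * n_extra
    phases += ["extra_hold"] * n_extra
    return PerturbationSchedule(
        experiment_id=experiment_id,
        rotation_by_trial=np.array(rotations),
        phase_labels=np.array(phases, dtype=object),
    )


def cursor_from_hand(hand_angle: float, rotation: float) -> float:
    """Cursor angle produced by a hand angle under an imposed rotation."""
    return hand_angle + rotation


def observe_cursor(
    cursor_angle: float, condition: Condition, rng: np.random.Generator
) -> Optional[float]:
    """Noisy perceptual observation of the cursor; None when no cursor is shown."""
    if not condition.has_observation:
        return None
    sd = condition.observation_noise_sd
    if sd == 0:
        return float(cursor_angle)
    return float(cursor_angle + rng.normal(0.0, sd))


def is_hit(cursor_angle: float, geometry: RewardGeometry) -> bool:
    """True when the cursor crosses within the target zone (boundary inclusive)."""
    return abs(cursor_angle - geometry.target_direction) <= geometry.half_width


def reward(cursor_angle: float, motor_command: float, geometry: RewardGeometry) -> float:
    """Scalar reward: hit indicator minus the quadratic motor cost."""
    hit = 1.0 if is_hit(cursor_angle, geometry) else 0.0
    return hit - geometry.motor_cost_scale * motor_command**2


@dataclass
class TrialRecord:
    """One reach: inputs, outcome, and the learner internals that produced it.

    ``observed_cursor`` is None when no cursor was shown.  ``search_noise``
    and ``motor_noise`` are the realized exploration and execution noise;
    ``p_hat_pre``/``x_r_pre`` are the memory states the action was computed
    from, so the command decomposes as
    ``command = target - p_hat_pre + x_r_pre + search_noise`` exactly.
    """

    trial_index: int
    phase: str
    target_direction: float
    imposed_rotation: float
    motor_command: float
    hand_angle: float
    cursor_angle: float
    observed_cursor: Optional[float]
    rewarded: int
    cursor_shown: bool
    search_noise: float = 0.0
    motor_noise: float = 0.0
    p_hat_pre: float = 0.0
    x_r_pre: float = 0.0
    p_hat_post: float = 0.0
    x_r_post: float = 0.0
    h_hat: float = 0.0
    value_post: float = 0.0
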