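"""Synthetic subjects: adaptation series plus localization and
generalization probes.

The generative learner produces each subject's adaptation series; the
probe responses are layered on phenomenologically, because the scalar
learner has no mechanism for direction-tuned generalization:

* localization probes store the pointing error relative to the actual
  hand (pointing - hand), which for a remapped subject equals a fraction
  ``remap_fraction`` of the terminal perturbation estimate plus noise;
* generalization probes transfer the adaptation to neighbouring target
  directions with a Gaussian (or cosine) falloff of width
  ``generalization_width``.

Cohort-level structure (e.g. the coupling between sensory remapping and
generalization width across endpoint-feedback subjects) is imposed by the
config sampler: a single latent reliance-on-vision variable can drive both.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List, Optional

import numpy as np
import pandas as pd

from .learner import LearnerParams
from .paradigm import Condition, RewardGeometry, build_schedule
from .simulate import SimulationResult, run_condition

__all__ = [
    "PROBE_DIRECTIONS",
    "SubjectConfig",
    "SubjectDataset",
    "generate_baseline_block",
    "generate_subject",
    "generate_cohort",
    "coupled_sampler",
    "independent_sampler",
]

#: The seven generalization probe directions, degrees.
PROBE_DIRECTIONS = (-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0)

#: Baseline-block target frequencies: 32/80 centre, 8/80 each peripheral.
_CENTER_COUNT = 32
_PERIPHERAL_COUNT = 8

_N_LOCALIZATION = 10  # localization micro-blocks per phase (PRE and POST)

#: Default experiment per condition: the localization experiment (EXP1) for
#: continuous-cursor and reward-only groups, the endpoint-error protocol
#: (EXP3) for EPE.
_DEFAULT_EXPERIMENT = {"ERR": "EXP1", "EPE": "EXP3", "RWD": "EXP1"}

#: Phenomenological defaults: fraction of the perturbation estimate expressed
#: in localization, and generalization width (degrees).  Error-based learning
#: remaps fully and generalizes broadly; reward-based learning not at all /
#: narrowly; endpoint feedback sits between.
_DEFAULT_REMAP_FRACTION = {"ERR": 1.0, "EPE": 0.6, "RWD": 0.0}
_DEFAULT_GENERALIZATION_WIDTH = {"ERR": 25.0, "EPE": 15.0, "RWD": 8.0}


@dataclass(frozen=True)
class SubjectConfig:
    """Ground-truth generating configuration of one synthetic subject."""

    condition: Condition
    learner_params: Optional[LearnerParams] = None
    remap_fraction: Optional[float] = None
    generalization_width: Optional[float] = None
    localization_noise_sd: float = 1.0
    seed: int = 0
    experiment_id: Optional[str] = None
    generalization_kind: str = "gaussian"

    def __post_init__(self):
        label = self.condition.label
        if self.learner_params is None:
            object.__setattr__(
                self, "learner_params", LearnerParams.for_condition(self.condition)
            )
        if self.remap_fraction is None:
            object.__setattr__(self, "remap_fraction", _DEFAULT_REMAP_FRACTION[label])
        if self.generalization_width is None:
            object.__setattr__(
                self, "generalization_width", _DEFAULT_GENERALIZATION_WIDTH[label]
            )
        if self.experiment_id is None:
            object.__setattr__(self, "experiment_id", _DEFAULT_EXPERIMENT[label])
        if not (0 <= self.remap_fraction <= 1):
            raise ValueError("remap_fraction must lie in [0, 1]")
        if self.generalization_width <= 0:
            raise ValueError("generalization_width must be positive")
        if self.localization_noise_sd < 0:
            raise ValueError("localization_noise_sd must be >= 0")
        if self.generalization_kind not in ("gaussian", "cosine"):
            raise ValueError("generalization_kind must be 'gaussian' or 'cosine'")


@dataclass
class SubjectDataset:
    """One synthetic subject: series, probes, and the generating truth."""

    trials: pd.DataFrame
    localization_pre: np.ndarray
    localization_post: np.ndarray
    generalization_pre: pd.DataFrame
    generalization_post: pd.DataFrame
    truth: SubjectConfig
    simulation: Optional[SimulationResult] = None

    def __post_init__(self):
        if len(self.localization_pre) != _N_LOCALIZATION or len(
            self.localization_post
        ) != _N_LOCALIZATION:
            raise ValueError(
                f"localization sequences must have length {_N_LOCALIZATION}"
            )


def generate_baseline_block(seed: Optional[int] = 0) -> np.ndarray:
    """80-trial baseline/probe target sequence: 32 centre, 8 per peripheral,
    order shuffled deterministically by seed."""
    targets = [0.0] * _CENTER_COUNT
    for d in PROBE_DIRECTIONS:
        if d != 0.0:
            targets += [d] * _PERIPHERAL_COUNT
    targets = np.array(targets)
    rng = np.random.default_rng(seed)
    rng.shuffle(targets)
    return targets


def _transfer(theta: np.ndarray, width: float, kind: str) -> np.ndarray:
    """Fractional transfer of adaptation to probe direction theta."""
    theta = np.asarray(theta, dtype=float)
    if kind == "gaussian":
        return np.exp(-(theta**2) / (2.0 * width**2))
    # raised-cosine alternative with the same interpretation of width
    out = np.where(
        np.abs(theta) >= 2.0 * width, 0.0, 0.5 * (1.0 + np.cos(np.pi * theta / (2.0 * width)))
    )
    return out


def _probe_block(
    rng: np.random.Generator,
    adaptation_change: float,
    width: float,
    kind: str,
    motor_noise_sd: float,
    seed_targets: int,
) -> pd.DataFrame:
    targets = generate_baseline_block(seed_targets)
    transfer = _transfer(targets, width, kind) * adaptation_change
    noise = rng.normal(0.0, motor_noise_sd, size=len(targets)) if motor_noise_sd > 0 else 0.0
    return pd.DataFrame(
        {"probe_deg": targets, "reach_deg": targets + transfer + noise}
    )


def generate_subject(config: SubjectConfig) -> SubjectDataset:
    """Generate one synthetic subject.

    The adaptation series comes from the generative learner on the
    condition's schedule.  POST localization errors are
    ``remap_fraction * terminal p_hat`` plus noise (signed toward the
    cursor); PRE errors are pure noise.  Generalization probes transfer the
    terminal reach change with the configured falloff.
    """
    schedule = build_schedule(config.experiment_id)
    sim = run_condition(
        config.learner_params,
        schedule,
        config.condition,
        geometry=RewardGeometry(),
        seed=config.seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    loc_sd = config.localization_noise_sd
    loc_noise = lambda: rng.normal(0.0, loc_sd, _N_LOCALIZATION) if loc_sd > 0 else np.zeros(_N_LOCALIZATION)
    localization_pre = loc_noise()
    shift = config.remap_fraction * sim.summary.terminal_p_hat
    localization_post = shift + loc_noise()

    reach = sim.trials["reach_deg"].to_numpy()
    baseline_mean = float(reach[schedule.phase_labels == "baseline"].mean())
    final_mean = float(reach[-sim.summary.final_window:].mean())
    adaptation_change = final_mean - baseline_mean  # signed reach change at 0 deg

    motor_sd = config.learner_params.motor_noise_sd
    gen_pre = _probe_block(
        rng, 0.0, config.generalization_width, config.generalization_kind,
        motor_sd, seed_targets=int(config.seed) * 2 + 11,
    )
    gen_post = _probe_block(
        rng, adaptation_change, config.generalization_width,
        config.generalization_kind, motor_sd, seed_targets=int(config.seed) * 2 + 12,
    )
    return SubjectDataset(
        trials=sim.trials,
        localization_pre=localization_pre,
        localization_post=localization_post,
        generalization_pre=gen_pre,
        generalization_post=gen_post,
        truth=config,
        simulation=sim,
    )


def generate_cohort(
    n_subjects: int,
    config_sampler: Callable[[np.random.Generator], SubjectConfig],
    seed: Optional[int] = 0,
) -> List[SubjectDataset]:
    """Independent subjects from a config sampler.

    The sampler receives a cohort-level generator and returns a
    :class:`SubjectConfig`; each subject is re-seeded deterministically from
    the cohort seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        cfg = config_sampler(rng)
        cfg = replace(cfg, seed=int(rng.integers(0, 2**31 - 1)))
        subjects.append(generate_subject(cfg))
    return subjects


def coupled_sampler(
    condition: Optional[Condition] = None,
    coupling: float = 1.0,
    reliance_range: tuple = (0.15, 1.0),
    width_range: tuple = (5.0, 30.0),
    localization_noise_sd: float = 1.0,
) -> Callable[[np.random.Generator], SubjectConfig]:
    """Sampler with a latent reliance-on-vision variable driving both the
    remapping fraction and the generalization width.

    With ``coupling = 1`` the width is fully determined by the same latent
    as the remap fraction (strong negative illusion-generalization
    correlation under the negative-rotation convention); ``coupling = 0``
    makes them independent.
    """
    if not (0 <= coupling <= 1):
        raise ValueError("coupling must lie in [0, 1]")
    condition = condition or Condition.from_label("EPE")

    def sampler(rng: np.random.Generator) -> SubjectConfig:
        z = rng.uniform(*reliance_range)
        z_w = coupling * z + (1.0 - coupling) * rng.uniform(*reliance_range)
        lo, hi = reliance_range
        frac = (z_w - lo) / (hi - lo)
        width = width_range[0] + frac * (width_range[1] - width_range[0])
        return SubjectConfig(
            condition=condition,
            remap_fraction=z,
            generalization_width=width,
            localization_noise_sd=localization_noise_sd,
        )

    return sampler


def independent_sampler(
    condition: Optional[Condition] = None, **kwargs
) -> Callable[[np.random.Generator], SubjectConfig]:
    """Null sampler: remap fraction and generalization width uncoupled."""
    return coupled_sampler(condition=condition, coupling=0.0, **kwargs)
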