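"""Readers and writers for trial tables, subject directories, and configs.

Trial tables are headered CSV with the interchange columns
``trial, phase, target_deg, rotation_deg, reach_deg, cursor_deg,
observed_deg, rewarded, cursor_shown`` (observed_deg blank when no cursor
was shown); simulator outputs keep their extra diagnostic columns.  A
subject directory holds ``trials.csv``, ``localization.json``,
``generalization.csv`` and ``truth.json``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .cohort import SubjectConfig, SubjectDataset
from .learner import LearnerParams
from .paradigm import Condition

__all__ = [
    "CORE_TRIAL_COLUMNS",
    "write_trials",
    "read_trials",
    "write_subject",
    "read_subject",
    "load_paradigm_config",
    "dump_params",
]

CORE_TRIAL_COLUMNS = [
    "trial", "phase", "target_deg", "rotation_deg", "reach_deg",
    "cursor_deg", "observed_deg", "rewarded", "cursor_shown",
]


def write_trials(trials: pd.DataFrame, path: Union[str, Path]) -> None:
    missing = set(CORE_TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns {sorted(missing)}")
    ordered = CORE_TRIAL_COLUMNS + [c for c in trials.columns if c not in CORE_TRIAL_COLUMNS]
    trials[ordered].to_csv(path, index=False)


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CORE_TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _config_to_dict(config: SubjectConfig) -> dict:
    return {
        "condition": {
            "label": config.condition.label,
            "observation_noise_sd": config.condition.observation_noise_sd,
        },
        "learner_params": dataclasses.asdict(config.learner_params),
        "remap_fraction": config.remap_fraction,
        "generalization_width": config.generalization_width,
        "localization_noise_sd": config.localization_noise_sd,
        "seed": config.seed,
        "experiment_id": config.experiment_id,
        "generalization_kind": config.generalization_kind,
    }


def _config_from_dict(d: dict) -> SubjectConfig:
    cond = Condition.from_label(
        d["condition"]["label"], d["condition"].get("observation_noise_sd")
    )
    return SubjectConfig(
        condition=cond,
        learner_params=LearnerParams(**d["learner_params"]),
        remap_fraction=d["remap_fraction"],
        generalization_width=d["generalization_width"],
        localization_noise_sd=d["localization_noise_sd"],
        seed=d["seed"],
        experiment_id=d["experiment_id"],
        generalization_kind=d.get("generalization_kind", "gaussian"),
    )


def write_subject(dataset: SubjectDataset, directory: Union[str, Path]) -> Path:
    """Write one subject to a directory; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_trials(dataset.trials, directory / "trials.csv")
    with open(directory / "localization.json", "w") as fh:
        json.dump(
            {
                "pre": list(map(float, dataset.localization_pre)),
                "post": list(map(float, dataset.localization_post)),
                "convention": "pointing error relative to actual hand, degrees",
            },
            fh,
            indent=1,
        )
    gen = pd.concat(
        [
            dataset.generalization_pre.assign(phase="pre"),
            dataset.generalization_post.assign(phase="post"),
        ],
        ignore_index=True,
    )
    gen.to_csv(directory / "generalization.csv", index=False)
    with open(directory / "truth.json", "w") as fh:
        json.dump(_config_to_dict(dataset.truth), fh, indent=1)
    return directory


def read_subject(directory: Union[str, Path]) -> SubjectDataset:
    directory = Path(directory)
    trials = read_trials(directory / "trials.csv")
    with open(directory / "localization.json") as fh:
        loc = json.load(fh)
    gen = pd.read_csv(directory / "generalization.csv")
    pre = gen[gen["phase"] == "pre"][["probe_deg", "reach_deg"]].reset_index(drop=True)
    post = gen[gen["phase"] == "post"][["probe_deg", "reach_deg"]].reset_index(drop=True)
    with open(directory / "truth.json") as fh:
        truth = _config_from_dict(json.load(fh))
    return SubjectDataset(
        trials=trials,
        localization_pre=np.asarray(loc["pre"], dtype=float),
        localization_post=np.asarray(loc["post"], dtype=float),
        generalization_pre=pre,
        generalization_post=post,
        truth=truth,
    )


def load_paradigm_config(path: Union[str, Path]) -> dict:
    """Load a paradigm YAML config: experiment, condition, noise overrides,
    seed.  Returns a dict with resolved Condition and defaults filled in."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    label = raw.get("condition", "ERR")
    cond = Condition.from_label(label, raw.get("observation_noise_sd"))
    params = LearnerParams.for_condition(cond, **(raw.get("learner_params") or {}))
    return {
        "experiment": raw.get("experiment", "EXP1"),
        "condition": cond,
        "learner_params": params,
        "seed": raw.get("seed", 0),
    }


def dump_params(params: LearnerParams, path: Union[str, Path]) -> None:
    """Dump all learner constants alongside a simulation output."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=True)
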