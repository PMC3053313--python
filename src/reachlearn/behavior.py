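"""Behavioural indices and group-level descriptive statistics.

Per subject: adaptation amount, final-window reach variability, the
localization illusion index (PRE-to-POST change in hand-pointing error),
the normalized generalization index, and the reward fraction.  Across
subjects: the illusion-generalization correlation and per-condition group
tables with descriptive pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import PROBE_DIRECTIONS, SubjectDataset
from .paradigm import build_schedule
from .simulate import summarize

__all__ = [
    "SubjectIndices",
    "illusion_index",
    "generalization_index",
    "subject_indices",
    "cohort_correlation",
    "group_report",
    "GroupReport",
]


@dataclass(frozen=True)
class SubjectIndices:
    """Scalar behavioural indices of one subject."""

    condition: str
    adaptation: float
    reach_sd_final100: float
    illusion_index: float
    generalization_index: float
    reward_fraction: float

    def __post_init__(self):
        for name in ("adaptation", "reach_sd_final100", "illusion_index",
                     "generalization_index", "reward_fraction"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0 <= self.reward_fraction <= 1):
            raise ValueError("reward_fraction must lie in [0, 1]")


def illusion_index(localization_pre: Sequence[float],
                   localization_post: Sequence[float]) -> float:
    """Signed PRE-to-POST change in mean localization error (degrees)."""
    pre = np.asarray(localization_pre, dtype=float)
    post = np.asarray(localization_post, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("localization sequences must be non-empty")
    return float(post.mean() - pre.mean())


def _per_direction_change(pre: pd.DataFrame, post: pd.DataFrame) -> pd.Series:
    """Mean reach change per probe direction, relative to the probe target."""
    pre_err = (pre["reach_deg"] - pre["probe_deg"]).groupby(pre["probe_deg"]).mean()
    post_err = (post["reach_deg"] - post["probe_deg"]).groupby(post["probe_deg"]).mean()
    return post_err - pre_err


def generalization_index(
    probe_table_pre: pd.DataFrame,
    probe_table_post: pd.DataFrame,
    adaptation: float,
) -> float:
    """Mean peripheral transfer normalized by the transfer at the trained
    direction; ~1 for flat (broad) generalization, ~0 for none.

    The normalizer is the measured change at 0 degrees when available,
    otherwise the supplied adaptation amount; a zero normalizer raises.
    """
    change = _per_direction_change(probe_table_pre, probe_table_post)
    directions = set(np.round(change.index.to_numpy(), 6))
    if not set(PROBE_DIRECTIONS) <= directions:
        missing = sorted(set(PROBE_DIRECTIONS) - directions)
        raise ValueError(f"probe tables must cover directions {missing}")
    center = float(change.loc[0.0]) if 0.0 in change.index else float(adaptation)
    if center == 0:
        raise ValueError("zero adaptation at the trained direction: index undefined")
    peripheral = change.drop(index=0.0)
    return float((peripheral / center).mean())


def subject_indices(dataset: SubjectDataset, final_window: int = 100) -> SubjectIndices:
    """All behavioural indices of one subject dataset."""
    schedule = build_schedule(dataset.truth.experiment_id)
    trials = dataset.trials
    stats = summarize(
        trials,
        schedule,
        trials["p_hat_deg"].to_numpy(dtype=float),
        trials["h_hat_deg"].to_numpy(dtype=float),
        final_window=final_window,
    )
    ill = illusion_index(dataset.localization_pre, dataset.localization_post)
    gen = generalization_index(
        dataset.generalization_pre, dataset.generalization_post, stats.adaptation
    )
    return SubjectIndices(
        condition=dataset.truth.condition.label,
        adaptation=stats.adaptation,
        reach_sd_final100=stats.reach_sd_final100,
        illusion_index=ill,
        generalization_index=gen,
        reward_fraction=stats.reward_fraction,
    )


def cohort_correlation(
    indices: Sequence[SubjectIndices], signed: bool = True
) -> Tuple[float, int]:
    """Pearson correlation of illusion vs. generalization index across
    subjects.

    ``signed=True`` correlates the signed illusion values (under a negative
    rotation, stronger remapping makes the illusion more negative, so a
    vision-reliance coupling yields a negative R); ``signed=False`` uses
    magnitudes.
    """
    if len(indices) < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    ill = np.array([s.illusion_index for s in indices], dtype=float)
    if not signed:
        ill = np.abs(ill)
    gen = np.array([s.generalization_index for s in indices], dtype=float)
    if np.std(ill) == 0 or np.std(gen) == 0:
        raise ValueError("correlation undefined for a constant index column")
    r, _ = sps.pearsonr(ill, gen)
    return float(r), len(indices)


_INDEX_FIELDS = (
    "adaptation", "reach_sd_final100", "illusion_index",
    "generalization_index", "reward_fraction",
)


@dataclass
class GroupReport:
    """Per-condition index means with descriptive pairwise contrasts."""

    table: pd.DataFrame
    pairwise: pd.DataFrame
    variability_ordering_ok: Optional[bool]

    def to_markdown(self) -> str:
        lines = ["## Group report (descriptive)", "", self.table.to_markdown(), ""]
        if len(self.pairwise):
            lines += ["### Pairwise contrasts (descriptive t-tests)", "",
                      self.pairwise.to_markdown(), ""]
        if self.variability_ordering_ok is not None:
            lines.append(
                f"Reach-variability ordering ERR < EPE < RWD: "
                f"{'satisfied' if self.variability_ordering_ok else 'violated'}"
            )
        return "\n".join(lines)


def group_report(cohorts: Dict[str, List[SubjectIndices]]) -> GroupReport:
    """Summarize cohorts of per-subject indices, one row per condition.

    Illusion magnitudes are reported unsigned in the group table (signed
    values stay in the per-subject records).  SE is NaN for single-subject
    cohorts.  All tests are descriptive, uncorrected.
    """
    if len(cohorts) < 2:
        raise ValueError("group_report needs at least 2 conditions")
    rows = []
    for label, subjects in cohorts.items():
        row = {"condition": label, "n": len(subjects)}
        for name in _INDEX_FIELDS:
            vals = np.array([getattr(s, name) for s in subjects], dtype=float)
            if name == "illusion_index":
                vals = np.abs(vals)
            row[f"{name}_mean"] = float(vals.mean())
            row[f"{name}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("condition")

    pair_rows = []
    labels = list(cohorts)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            for name in _INDEX_FIELDS:
                va = np.array([getattr(s, name) for s in cohorts[a]], dtype=float)
                vb = np.array([getattr(s, name) for s in cohorts[b]], dtype=float)
                if name == "illusion_index":
                    va, vb = np.abs(va), np.abs(vb)
                diff = float(va.mean() - vb.mean())
                if len(va) > 1 and len(vb) > 1:
                    t, p = sps.ttest_ind(va, vb, equal_var=False)
                else:
                    t, p = np.nan, np.nan
                pair_rows.append(
                    {"contrast": f"{a} - {b}", "index": name, "mean_diff": diff,
                     "t_descriptive": float(t), "p_descriptive": float(p)}
                )
    pairwise = pd.DataFrame(pair_rows)

    ordering = None
    if {"ERR", "EPE", "RWD"} <= set(labels):
        sd = {lab: table.loc[lab, "reach_sd_final100_mean"] for lab in ("ERR", "EPE", "RWD")}
        ordering = bool(sd["ERR"] < sd["EPE"] < sd["RWD"])
    return GroupReport(table=table, pairwise=pairwise, variability_ordering_ok=ordering)
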