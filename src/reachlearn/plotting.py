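"""Convenience plots: adaptation time course and generalization curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .simulate import SimulationResult

__all__ = ["plot_simulation", "plot_generalization"]


def plot_simulation(result: SimulationResult, ax=None):
    """Reach angle, perturbation estimate, and estimated vs. actual hand."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    trials = result.trials
    k = trials["trial"]
    ax.plot(k, -result.schedule.rotation_by_trial, color="0.6", lw=1,
            label="ideal compensation (-rotation)")
    ax.plot(k, trials["reach_deg"], lw=0.6, alpha=0.7, label="reach")
    ax.plot(k, result.p_hat_by_trial, lw=1.2, label=r"$\hat{p}$ (remapping)")
    ax.plot(k, trials["x_r_deg"], lw=1.2, label=r"$x_r$ (reward memory)")
    ax.set_xlabel("trial")
    ax.set_ylabel("degrees")
    ax.set_title(
        f"{result.condition.label} / {result.schedule.experiment_id} "
        f"(reward fraction {result.summary.reward_fraction:.2f})"
    )
    ax.legend(fontsize=8)
    return ax


def plot_generalization(pre, post, ax=None):
    """Mean reach change per probe direction (POST - PRE)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    pre_err = (pre["reach_deg"] - pre["probe_deg"]).groupby(pre["probe_deg"]).mean()
    post_err = (post["reach_deg"] - post["probe_deg"]).groupby(post["probe_deg"]).mean()
    change = post_err - pre_err
    ax.plot(change.index, change.values, "o-")
    ax.set_xlabel("probe direction (deg)")
    ax.set_ylabel("reach change (deg)")
    ax.axhline(0, color="0.7", lw=0.8)
    return ax
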