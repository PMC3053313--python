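"""Dual-memory trial-by-trial model fitting.

Decomposes an observed reach-angle series into two memory trajectories —
``x_p`` (perturbation compensation driven by sensory prediction error, the
negated Kalman estimate) and ``x_r`` (policy offset driven by reward
prediction error) — plus a residual active-search-noise sequence::

    reach_k = x_p[k] + x_r[k] + eta[k]

The residual on each trial feeds the actor-critic update (the executed
exploration), and the sensory prediction error is formed from the
experimenter-imposed rotation, so both memories are deterministic
functions of the data given the parameters.  The unknown parameters are
found by bounded multi-start nonlinear least squares on the residual
sequence, i.e. by minimizing the summed squared search noise.

The public surface follows the statsmodels convention: build a
:class:`DualMemoryModel` from data, call :meth:`~DualMemoryModel.fit`, and
read estimates, trajectories and diagnostics off the returned
:class:`DualMemoryResults` (with a ``summary()`` table).  The module-level
functions :func:`forward_filter`, :func:`fit_subject` and :func:`decompose`
are thin wrappers over those objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .paradigm import Condition

__all__ = [
    "FilterParams",
    "DualMemoryModel",
    "DualMemoryResults",
    "FitResult",
    "forward_filter",
    "fit_subject",
    "decompose",
    "PARAM_MAPPINGS",
]

MIN_SERIES_LENGTH = 50

#: Free-parameter mappings (the printed fitted triples do not name their
#: components; the identity adopted here is a configuration point).
#: "process_noise": (observation variance, shared actor/critic rate, process
#: variance) for ERR/EPE.  "split_rates": (observation variance, critic rate,
#: actor rate) with the process variance fixed.  RWD always fits the pair
#: (actor rate, critic rate) with the estimator gain forced to zero.
PARAM_MAPPINGS = ("process_noise", "split_rates")


@dataclass(frozen=True)
class FilterParams:
    """Fully resolved parameters of the constrained forward filter."""

    observation_noise_var: float = 1.0
    actor_lr: float = 0.15
    critic_lr: float = 0.15
    process_noise_var: float = 0.01
    retention: float = 0.99
    discount: float = 0.9
    motor_cost_scale: float = 0.0
    gain_forced_zero: bool = False
    initial_uncertainty: float = 1.0


class DualMemoryModel:
    """Dual-memory state-space model of one subject's adaptation series.

    Parameters
    ----------
    reach : array-like
        Observed reach angle per trial, degrees.
    rotation : array-like
        Experimenter-imposed rotation per trial, degrees.
    rewarded : array-like
        Binary success flag per trial.
    condition : Condition or str
        Feedback condition; RWD forces the estimator gain to zero and
        reduces the free parameters to the actor/critic learning rates.
    param_mapping : {"process_noise", "split_rates"}
        Identity of the fitted triple for ERR/EPE (see module docstring).
    retention, discount, process_noise_var, motor_cost_scale : float
        Fixed (non-fitted) constants of the filter.
    """

    def __init__(
        self,
        reach,
        rotation,
        rewarded,
        condition,
        *,
        param_mapping: str = "process_noise",
        retention: float = 0.99,
        discount: float = 0.9,
        process_noise_var: float = 0.01,
        motor_cost_scale: float = 0.0,
        initial_uncertainty: float = 1.0,
    ):
        reach = np.asarray(reach, dtype=float)
        rotation = np.asarray(rotation, dtype=float)
        rewarded = np.asarray(rewarded, dtype=float)
        if not (len(reach) == len(rotation) == len(rewarded)):
            raise ValueError("reach, rotation and rewarded must have equal length")
        if len(reach) < MIN_SERIES_LENGTH:
            raise ValueError(
                f"series too short for identifiable fitting "
                f"(need >= {MIN_SERIES_LENGTH} trials, got {len(reach)})"
            )
        if not np.all(np.isfinite(reach)):
            raise ValueError("reach angles must be finite")
        if param_mapping not in PARAM_MAPPINGS:
            raise ValueError(f"param_mapping must be one of {PARAM_MAPPINGS}")
        if isinstance(condition, str):
            condition = Condition.from_label(condition)
        self.reach = reach
        self.rotation = rotation
        self.rewarded = rewarded
        self.condition = condition
        self.param_mapping = param_mapping
        self.retention = retention
        self.discount = discount
        self.process_noise_var = process_noise_var
        self.motor_cost_scale = motor_cost_scale
        self.initial_uncertainty = initial_uncertainty

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, condition, **kwargs) -> "DualMemoryModel":
        """Build from a trial table with reach_deg / rotation_deg / rewarded."""
        missing = {"reach_deg", "rotation_deg", "rewarded"} - set(df.columns)
        if missing:
            raise ValueError(f"trial table is missing columns {sorted(missing)}")
        return cls(
            df["reach_deg"], df["rotation_deg"], df["rewarded"], condition, **kwargs
        )

    # ------------------------------------------------------------------
    @property
    def n_free_params(self) -> int:
        return 2 if not self.condition.has_observation else 3

    @property
    def param_names(self) -> Tuple[str, ...]:
        if not self.condition.has_observation:
            return ("actor_lr", "critic_lr")
        if self.param_mapping == "process_noise":
            return ("observation_noise_var", "learning_rate", "process_noise_var")
        return ("observation_noise_var", "critic_lr", "actor_lr")

    def resolve_params(self, theta: Sequence[float]) -> FilterParams:
        """Map a free-parameter vector onto full filter parameters."""
        theta = [float(t) for t in theta]
        if len(theta) != self.n_free_params:
            raise ValueError(
                f"expected {self.n_free_params} free parameters, got {len(theta)}"
            )
        common = dict(
            retention=self.retention,
            discount=self.discount,
            motor_cost_scale=self.motor_cost_scale,
            initial_uncertainty=self.initial_uncertainty,
        )
        if not self.condition.has_observation:
            return FilterParams(
                actor_lr=theta[0],
                critic_lr=theta[1],
                process_noise_var=self.process_noise_var,
                gain_forced_zero=True,
                **common,
            )
        if self.param_mapping == "process_noise":
            return FilterParams(
                observation_noise_var=theta[0],
                actor_lr=theta[1],
                critic_lr=theta[1],
                process_noise_var=theta[2],
                **common,
            )
        return FilterParams(
            observation_noise_var=theta[0],
            critic_lr=theta[1],
            actor_lr=theta[2],
            process_noise_var=self.process_noise_var,
            **common,
        )

    # ------------------------------------------------------------------
    def filter(self, params: FilterParams) -> Dict[str, np.ndarray]:
        """Run the constrained learner forward against the observed reaches.

        On trial k the model predicts ``x_p[k] + x_r[k]``; the residual
        ``eta[k] = reach[k] - x_p[k] - x_r[k]`` is the inferred search
        noise, which drives the actor update; the imposed rotation drives
        the Kalman update of ``-x_p``.  All memories start at zero.
        """
        n = len(self.reach)
        x_p = np.zeros(n)
        x_r = np.zeros(n)
        eta = np.zeros(n)
        p_hat = 0.0
        P = params.initial_uncertainty
        xr = 0.0
        v = 0.0
        a = params.retention
        q = params.process_noise_var
        sigma2 = params.observation_noise_var
        gain_zero = params.gain_forced_zero
        lam = params.motor_cost_scale
        gamma = params.discount
        a_lr, c_lr = params.actor_lr, params.critic_lr
        reach, rotation, rewarded = self.reach, self.rotation, self.rewarded
        for k in range(n):
            x_p[k] = -p_hat
            x_r[k] = xr
            e = reach[k] - (x_p[k] + xr)
            eta[k] = e
            # actor-critic update from the logged reward
            r = rewarded[k] - lam * reach[k] ** 2
            delta = r + gamma * v - v
            v += c_lr * delta
            xr += a_lr * delta * e
            # Kalman update from the imposed rotation
            p_prior = a * p_hat
            P_prior = a * a * P + q
            if gain_zero:
                p_hat, P = p_prior, P_prior
            else:
                K = P_prior / (P_prior + sigma2)
                p_hat = p_prior + K * (rotation[k] - p_prior)
                P = (1.0 - K) * P_prior
        return {"x_p": x_p, "x_r": x_r, "eta": eta}

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self.filter(self.resolve_params(theta))["eta"]

    # ------------------------------------------------------------------
    def _bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        if not self.condition.has_observation:
            return np.array([0.0, 0.0]), np.array([1.0, 1.0])
        if self.param_mapping == "process_noise":
            return np.array([1e-6, 0.0, 1e-8]), np.array([1e4, 1.0, 10.0])
        return np.array([1e-6, 0.0, 0.0]), np.array([1e4, 1.0, 1.0])

    def _starts(self, n_starts: int, seed: Optional[int]) -> np.ndarray:
        lo, hi = self._bounds()
        sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
        unit = sampler.random(n_starts)
        starts = np.empty_like(unit)
        for j in range(len(lo)):
            is_variance = self.condition.has_observation and (
                j == 0 or (self.param_mapping == "process_noise" and j == 2)
            )
            if is_variance:
                # sample variances log-uniformly over a plausible range
                log_lo, log_hi = np.log10(max(lo[j], 1e-4)), np.log10(min(hi[j], 1e3))
                starts[:, j] = 10 ** (log_lo + unit[:, j] * (log_hi - log_lo))
            else:
                span_lo, span_hi = lo[j], min(hi[j], 0.9)
                starts[:, j] = span_lo + unit[:, j] * (span_hi - span_lo)
        return starts

    def fit(self, n_starts: int = 10, seed: Optional[int] = 0) -> "DualMemoryResults":
        """Bounded multi-start trust-region least squares on the residuals.

        Deterministic given ``seed`` (Latin-hypercube start points).  The
        best-of-starts solution is returned; per-start records are kept for
        diagnostics.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        lo, hi = self._bounds()
        starts = self._starts(n_starts, seed)
        records: List[dict] = []
        best = None
        for i, x0 in enumerate(starts):
            try:
                sol = least_squares(
                    self._residuals, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception as exc:  # pragma: no cover - optimizer blow-up
                records.append({"start": i, "x0": x0, "error": str(exc)})
                continue
            sse = float(np.sum(sol.fun**2))
            records.append(
                {"start": i, "x0": x0, "theta": sol.x, "sse": sse,
                 "status": sol.status, "success": bool(sol.success)}
            )
            if sol.success and (best is None or sse < best[1]):
                best = (sol, sse)
        if best is None:
            raise RuntimeError(
                f"all {n_starts} optimizer starts failed; records: {records}"
            )
        sol, sse = best
        return DualMemoryResults(self, sol.x, records, n_starts=n_starts, seed=seed)


class DualMemoryResults:
    """Fit output: parameter estimates, memory trajectories, diagnostics."""

    def __init__(self, model: DualMemoryModel, theta: np.ndarray,
                 start_records: List[dict], n_starts: int, seed: Optional[int]):
        self.model = model
        self.theta = np.asarray(theta, dtype=float)
        self.params = dict(zip(model.param_names, self.theta))
        traj = model.filter(model.resolve_params(self.theta))
        self.x_p_by_trial = traj["x_p"]
        self.x_r_by_trial = traj["x_r"]
        self.eta_by_trial = traj["eta"]
        self.sse = float(np.sum(self.eta_by_trial**2))
        self.search_noise_var_hat = float(np.var(self.eta_by_trial, ddof=0))
        self.n_starts = n_starts
        self.seed = seed
        self.start_records = start_records
        self.converged = any(r.get("success") for r in start_records)

    # ------------------------------------------------------------------
    def decompose(self, window: int = 80) -> Tuple[float, float, float]:
        """Terminal memory split: mean x_p and x_r over the final ``window``
        trials, plus the residual search-noise variance estimate."""
        n = len(self.x_p_by_trial)
        if window > n or window < 1:
            raise ValueError("window must be in [1, n_trials]")
        sl = slice(n - window, n)
        return (
            float(np.mean(self.x_p_by_trial[sl])),
            float(np.mean(self.x_r_by_trial[sl])),
            self.search_noise_var_hat,
        )

    def predicted_reach(self) -> np.ndarray:
        return self.x_p_by_trial + self.x_r_by_trial

    def summary(self, window: int = 80) -> str:
        """Plain-text summary table in the statsmodels style."""
        xp, xr, var_eta = self.decompose(window)
        lines = [
            "Dual-memory adaptation model fit",
            "=" * 46,
            f"condition:            {self.model.condition.label}",
            f"n trials:             {len(self.model.reach)}",
            f"free parameters:      {', '.join(self.model.param_names)}",
            f"param mapping:        {self.model.param_mapping}",
            f"starts (seed):        {self.n_starts} ({self.seed})",
            f"converged:            {self.converged}",
            "-" * 46,
        ]
        for name, val in self.params.items():
            lines.append(f"{name:<21s} {val: .5g}")
        lines += [
            "-" * 46,
            f"SSE (sum eta^2):      {self.sse:.5g}",
            f"search-noise var:     {var_eta:.5g}",
            f"terminal x_p (w={window}): {xp: .4g}",
            f"terminal x_r (w={window}): {xr: .4g}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "condition": self.model.condition.label,
            "param_mapping": self.model.param_mapping,
            "params": {k: float(v) for k, v in self.params.items()},
            "sse": self.sse,
            "search_noise_var": self.search_noise_var_hat,
            "converged": bool(self.converged),
            "n_starts": self.n_starts,
            "seed": self.seed,
            "x_p_by_trial": self.x_p_by_trial.tolist(),
            "x_r_by_trial": self.x_r_by_trial.tolist(),
            "eta_by_trial": self.eta_by_trial.tolist(),
        }


#: Backwards-compatible alias: a fit result *is* the results object.
FitResult = DualMemoryResults


# ----------------------------------------------------------------------
# module-level convenience wrappers


def forward_filter(
    series: pd.DataFrame, params: FilterParams, condition
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the constrained filter with known parameters over a trial table.

    Returns ``(x_p_by_trial, x_r_by_trial, eta_by_trial)``.
    """
    model = DualMemoryModel.from_dataframe(series, condition)
    if not model.condition.has_observation:
        params = FilterParams(**{**params.__dict__, "gain_forced_zero": True})
    traj = model.filter(params)
    return traj["x_p"], traj["x_r"], traj["eta"]


def fit_subject(
    series: pd.DataFrame,
    condition,
    n_starts: int = 10,
    seed: Optional[int] = 0,
    **model_kwargs,
) -> DualMemoryResults:
    """Fit one subject's trial table; see :meth:`DualMemoryModel.fit`."""
    model = DualMemoryModel.from_dataframe(series, condition, **model_kwargs)
    return model.fit(n_starts=n_starts, seed=seed)


def decompose(fit: DualMemoryResults, window: int = 80) -> Tuple[float, float, float]:
    """Terminal (x_p, x_r, search-noise variance) of a converged fit."""
    if not fit.converged:
        raise ValueError("decompose requires a converged fit")
    return fit.decompose(window)
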