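"""Ensemble summary statistics: equilibrium means/SDs, rank correlations with
theta, convergence half-times and tightness (coefficient-of-variation) metrics.

Statistics follow the standard ensemble protocol: each agent's variables are
time-averaged over the last ``last_k`` steps of a run, across-agent means and
standard deviations are formed per run, and runs are averaged with equal
weight.  Kendall rank correlations (tau-b, tie-corrected) between the
time-averaged variables and the material benefit-to-cost summary theta are
likewise computed per run and averaged.  Lower coefficients of variation
correspond to tighter norms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import RunResult, Trajectory
from .equilibrium import NonContractiveError, exact_fixed_point

__all__ = ["SummaryTable", "HalfTime", "VARIABLES", "equilibrium_stats",
           "kendall_tau", "half_time", "tightness_metrics"]

VARIABLES = ("x", "y", "y_exp", "x_exp")


class HalfTime(NamedTuple):
    """Convergence half-time; ``censored`` marks targets never reached, in
    which case ``value`` is the trajectory length."""

    value: float
    censored: bool


def kendall_tau(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Kendall rank correlation (tau-b, tie-corrected) with two-sided p-value.

    All-tied input in either argument leaves the correlation undefined:
    returns (nan, nan) with a warning.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("kendall_tau needs two equal-length 1-d arrays, n >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("all-tied input: Kendall correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.kendalltau(a, b, variant="b")
    return float(res.statistic), float(res.pvalue)


def half_time(trajectory: Trajectory, equilibrium_value: float) -> HalfTime:
    """Time for the group-mean action to halve its distance to equilibrium.

    Measured on the recorded group-mean action with linear interpolation
    between recorded steps; a trajectory starting at the equilibrium has
    half-time 0, and one that never reaches half distance is censored at its
    final recorded time.
    """
    d = np.abs(trajectory.mean_x - equilibrium_value)
    t = trajectory.times.astype(float)
    if d[0] == 0:
        return HalfTime(0.0, False)
    target = 0.5 * d[0]
    below = np.nonzero(d <= target)[0]
    if below.size == 0:
        return HalfTime(float(t[-1]), True)
    k = int(below[0])
    if k == 0:  # pragma: no cover - d[0] > target by construction
        return HalfTime(0.0, False)
    frac = (d[k - 1] - target) / (d[k - 1] - d[k])
    return HalfTime(float(t[k - 1] + frac * (t[k] - t[k - 1])), False)


@dataclass
class SummaryTable:
    """Run-averaged equilibrium statistics, one row per variable.

    ``table`` columns: mean, sd (across agents), cv, kendall_tau, kendall_p,
    significant (p < 0.05), half_time (mean over uncensored runs; the
    group-mean action only), frac_censored.  ``per_run`` keeps the per-run
    ingredients for downstream ensemble-level analyses.
    """

    table: pd.DataFrame
    per_run: dict[str, np.ndarray]
    last_k: int
    n_runs: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="variable")

    def to_json(self) -> dict:
        return {
            "last_k": self.last_k,
            "n_runs": self.n_runs,
            "variables": {
                v: {c: (None if pd.isna(val) else (bool(val) if c == "significant"
                                                   else float(val)))
                    for c, val in self.table.loc[v].items()}
                for v in self.table.index
            },
        }


def _per_run_stats(result: RunResult, last_k: int):
    tail = result.trajectory.tail_time_average(last_k)
    vals = {v: getattr(tail, v) for v in VARIABLES}
    theta = result.group.theta
    means = {v: float(vals[v].mean()) for v in VARIABLES}
    sds = {v: float(vals[v].std(ddof=1)) for v in VARIABLES}
    taus, ps = {}, {}
    theta_ok = np.all(np.isfinite(theta)) and np.ptp(theta) > 0
    for v in VARIABLES:
        if theta_ok and np.ptp(vals[v]) > 0:
            tau, p = kendall_tau(vals[v], theta)
        else:
            tau, p = float("nan"), float("nan")
        taus[v], ps[v] = tau, p
    return means, sds, taus, ps


def equilibrium_stats(ensemble: Sequence[RunResult], last_k: int = 100,
                      compute_half_time: bool = True) -> SummaryTable:
    """Ensemble summary over the last ``last_k`` steps of every run.

    Half-times are measured against each run's exact deterministic fixed
    point (group-mean action); runs whose fixed point is unavailable (non-
    contractive instance) or whose half-time is censored are excluded from
    the half-time average and counted in ``frac_censored``.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    rows = {v: {"mean": [], "sd": [], "kendall_tau": [], "kendall_p": []}
            for v in VARIABLES}
    half_times, censored = [], 0
    per_run = {f"{k}_{v}": [] for v in VARIABLES for k in ("mean", "sd", "tau")}
    per_run["theta_mean"] = []
    for res in ensemble:
        means, sds, taus, ps = _per_run_stats(res, last_k)
        for v in VARIABLES:
            rows[v]["mean"].append(means[v])
            rows[v]["sd"].append(sds[v])
            rows[v]["kendall_tau"].append(taus[v])
            rows[v]["kendall_p"].append(ps[v])
            per_run[f"mean_{v}"].append(means[v])
            per_run[f"sd_{v}"].append(sds[v])
            per_run[f"tau_{v}"].append(taus[v])
        th = res.group.theta
        per_run["theta_mean"].append(
            float(np.nanmean(th)) if np.any(np.isfinite(th)) else float("nan"))
        if compute_half_time:
            try:
                eq = float(exact_fixed_point(res.group).x.mean())
            except NonContractiveError:
                censored += 1
                continue
            ht = half_time(res.trajectory, eq)
            if ht.censored:
                censored += 1
            else:
                half_times.append(ht.value)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        records = []
        for v in VARIABLES:
            mean_p = float(np.nanmean(rows[v]["kendall_p"]))
            mean_sd = float(np.mean(rows[v]["sd"]))
            mean_mean = float(np.mean(rows[v]["mean"]))
            records.append({
                "mean": mean_mean,
                "sd": mean_sd,
                "cv": mean_sd / mean_mean if mean_mean != 0 else float("nan"),
                "kendall_tau": float(np.nanmean(rows[v]["kendall_tau"])),
                "kendall_p": mean_p,
                "significant": bool(mean_p < 0.05) if np.isfinite(mean_p) else False,
                "half_time": float(np.mean(half_times)) if half_times else float("nan"),
                "frac_censored": (censored / len(ensemble)) if compute_half_time
                                 else float("nan"),
            })
    table = pd.DataFrame(records, index=list(VARIABLES))
    return SummaryTable(table=table, per_run={k: np.asarray(v) for k, v in per_run.items()},
                        last_k=last_k, n_runs=len(ensemble))


def tightness_metrics(table: SummaryTable) -> pd.Series:
    """Coefficient of variation sd/mean per variable; lower is tighter.

    Zero means leave the CV undefined (NaN, with a warning).
    """
    means = table.table["mean"]
    if (means == 0).any():
        warnings.warn("zero mean: coefficient of variation undefined", stacklevel=2)
    cv = table.table["sd"] / means.replace(0, np.nan)
    cv.name = "cv"
    return cv
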