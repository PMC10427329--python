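"""Stochastic coupled dynamics of actions, attitudes and beliefs.

One time step (all agents in parallel):

1. each agent is independently marked *revising* with probability
   ``revision_prob``;
2. every revising agent posts the closed-form best response computed from its
   current attitude and beliefs (plus a small Gaussian error, clipped at 0);
   non-revising agents keep their previous action;
3. every agent observes X_i, the mean of the *other* n-1 posted actions
   (stale actions of non-revisers are observed like any other);
4. every revising agent applies the damped belief update with its X_i (plus
   Gaussian error on each updated component, clipped at 0).

Posting is simultaneous: all X_i are computed from the same posted vector.
Noise enters the action and belief channels independently and each channel
can be switched off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .model_core import AgentState, best_response, update_beliefs
from .population import Group, PopulationConfig, build_group, initial_states

__all__ = ["SimConfig", "Trajectory", "RunResult", "step", "run", "run_ensemble",
           "leave_one_out_mean"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation protocol: length, revision schedule, noise and recording."""

    steps: int = 1000
    revision_prob: float = 0.5
    noise_sd: float = 0.01
    record_every: int = 1
    seed: int = 0
    noise_on_actions: bool = True
    noise_on_beliefs: bool = True

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be non-negative")
        if not 0.0 <= self.revision_prob <= 1.0:
            raise ValueError("revision_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.record_every < 1:
            raise ValueError("record_every must be a positive integer")


def leave_one_out_mean(x: np.ndarray) -> np.ndarray:
    """X_i = mean of the other agents' actions, for every agent at once."""
    n = x.shape[0]
    return (x.sum() - x) / (n - 1)


def step(group: Group, states: AgentState, sim: SimConfig,
         rng: np.random.Generator) -> AgentState:
    """Advance the group one time step; returns the new state (input untouched)."""
    n = group.n
    revising = rng.random(n) < sim.revision_prob

    br = best_response(group.pc, group.nw, group.authority, states)
    if sim.noise_on_actions and sim.noise_sd > 0:
        br = br + rng.normal(0.0, sim.noise_sd, n)
    x_new = np.where(revising, np.maximum(0.0, br), states.x)

    X = leave_one_out_mean(x_new)

    posted = replace(states, x=x_new)
    updated = update_beliefs(group.bw, posted, X, group.authority)
    if sim.noise_on_beliefs and sim.noise_sd > 0:
        noise = rng.normal(0.0, sim.noise_sd, (3, n))
        updated = replace(
            updated,
            y=np.maximum(0.0, updated.y + noise[0]),
            y_exp=np.maximum(0.0, updated.y_exp + noise[1]),
            x_exp=np.maximum(0.0, updated.x_exp + noise[2]),
        )
    return AgentState(
        x=x_new,
        y=np.where(revising, updated.y, states.y),
        x_exp=np.where(revising, updated.x_exp, states.x_exp),
        y_exp=np.where(revising, updated.y_exp, states.y_exp),
    )


@dataclass
class Trajectory:
    """Recorded history of one run: per-agent states plus observed peer means.

    Arrays have shape (n_recorded, n_agents); ``times[k]`` is the step index
    of row k (0 is the initial state).  ``X_obs`` holds each agent's
    leave-self-out mean of the posted actions at the recorded step.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    x_exp: np.ndarray
    y_exp: np.ndarray
    X_obs: np.ndarray

    @property
    def n_agents(self) -> int:
        return self.x.shape[1]

    @property
    def mean_x(self) -> np.ndarray:
        return self.x.mean(axis=1)

    @property
    def mean_y(self) -> np.ndarray:
        return self.y.mean(axis=1)

    @property
    def mean_x_exp(self) -> np.ndarray:
        return self.x_exp.mean(axis=1)

    @property
    def mean_y_exp(self) -> np.ndarray:
        return self.y_exp.mean(axis=1)

    def state_at(self, row: int) -> AgentState:
        return AgentState(x=self.x[row], y=self.y[row],
                          x_exp=self.x_exp[row], y_exp=self.y_exp[row])

    def tail_time_average(self, last_k: int) -> AgentState:
        """Per-agent averages over recorded rows within the last ``last_k`` steps."""
        cutoff = self.times[-1] - last_k
        sel = self.times > cutoff
        if not sel.any():
            raise ValueError("trajectory has no recorded rows in the requested tail")
        return AgentState(
            x=self.x[sel].mean(axis=0), y=self.y[sel].mean(axis=0),
            x_exp=self.x_exp[sel].mean(axis=0), y_exp=self.y_exp[sel].mean(axis=0),
        )

    def to_dataframe(self, run: int | None = None) -> pd.DataFrame:
        """Tidy long format: one row per (step, agent)."""
        k, n = self.x.shape
        df = pd.DataFrame({
            "step": np.repeat(self.times, n),
            "agent": np.tile(np.arange(n), k),
            "x": self.x.ravel(),
            "y": self.y.ravel(),
            "x_exp": self.x_exp.ravel(),
            "y_exp": self.y_exp.ravel(),
            "X_obs": self.X_obs.ravel(),
        })
        if run is not None:
            df.insert(0, "run", run)
        return df


def run(group: Group, init_states: AgentState, sim: SimConfig,
        rng: np.random.Generator | None = None) -> Trajectory:
    """Iterate :func:`step` for ``sim.steps`` steps, recording every
    ``record_every`` steps (the initial and final states always included)."""
    rng = np.random.default_rng(sim.seed) if rng is None else rng
    states = init_states.copy()
    rows_t, rows = [], []

    def record(t, st):
        rows_t.append(t)
        rows.append((st.x.copy(), st.y.copy(), st.x_exp.copy(), st.y_exp.copy(),
                     leave_one_out_mean(st.x)))

    record(0, states)
    for t in range(1, sim.steps + 1):
        states = step(group, states, sim, rng)
        if t % sim.record_every == 0 or t == sim.steps:
            record(t, states)
    stacked = [np.stack([r[i] for r in rows]) for i in range(5)]
    return Trajectory(times=np.asarray(rows_t), x=stacked[0], y=stacked[1],
                      x_exp=stacked[2], y_exp=stacked[3], X_obs=stacked[4])


@dataclass
class RunResult:
    """One ensemble member: the sampled group and its trajectory."""

    run: int
    group: Group
    trajectory: Trajectory
    group_seed: int
    sim_seed: int


def run_ensemble(cfg: PopulationConfig, sim: SimConfig, n_runs: int,
                 master_seed: int, init_low: float = 0.0,
                 init_high: float = 0.1) -> list[RunResult]:
    """Independent replicate runs, each with a freshly sampled group.

    Per-run seeds are spawned deterministically from ``master_seed``; run r
    uses one stream for the group/initial-state draw and one for the
    dynamics, so ensembles are reproducible and runs are independent.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    ss = np.random.SeedSequence(master_seed)
    results = []
    for r, child in enumerate(ss.spawn(n_runs)):
        gseed, sseed = (int(s) for s in child.generate_state(2) % (2 ** 31))
        grng = np.random.default_rng(gseed)
        group = build_group(cfg, grng)
        init = initial_states(cfg.n, grng, init_low, init_high)
        traj = run(group, init, sim, np.random.default_rng(sseed))
        results.append(RunResult(run=r, group=group, trajectory=traj,
                                 group_seed=gseed, sim_seed=sseed))
    return results
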