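"""Sampling heterogeneous groups of agents.

A group is built from a :class:`PopulationConfig`: per-agent game primitives
are drawn from moment-parameterised log-normal distributions (shares from a
broken-stick partition for the public-goods game), base normative weights
a1..a4 and belief-update coefficients are drawn on the same scale, and the
normative weights are then scaled by the dial ``epsilon`` in [0, 1].  At
``epsilon = 0`` all normative terms vanish and agents play myopic material
best response (the evolutionary-game-theory baseline); at ``epsilon = 1``
each normative term carries, in expectation, the same weight as the
quadratic material term.

All randomness flows through a single :class:`numpy.random.Generator`, so a
(config, seed) pair reproduces a group bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .games import (
    CPRParams,
    CoordinationParams,
    GameSpec,
    GenericParams,
    PGGQuadParams,
    payoff_coeffs,
)
from .model_core import (
    AgentState,
    Authority,
    BeliefWeights,
    NonConcavePayoffError,
    NormWeights,
    PayoffCoeffs,
    theta,
)

__all__ = [
    "PopulationConfig",
    "Group",
    "sample_lognormal",
    "sample_broken_stick",
    "build_group",
    "initial_states",
    "DEFAULT_DISTS",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_lognormal(mean: float, sd: float, n: int, seed) -> np.ndarray:
    """i.i.d. log-normal draws with the given *distribution* mean and sd.

    Moment-matched parameterisation: sigma^2 = ln(1 + sd^2/mean^2),
    mu = ln(mean) - sigma^2/2, so the sample mean/sd converge to the
    arguments.  ``sd = 0`` degenerates to the constant ``mean``.
    """
    if mean <= 0:
        raise ValueError("log-normal mean must be positive")
    if sd < 0:
        raise ValueError("log-normal sd must be non-negative")
    if sd == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return _rng(seed).lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def sample_broken_stick(n: int, seed) -> np.ndarray:
    """n non-negative shares summing to 1: gaps between sorted uniform breaks.

    Each share has expectation 1/n; no ordering is imposed on the shares.
    """
    if n < 1:
        raise ValueError("need at least one share")
    if n == 1:
        return np.ones(1)
    breaks = np.sort(_rng(seed).uniform(size=n - 1))
    return np.diff(np.concatenate(([0.0], breaks, [1.0])))


# Per-game default (mean, sd) recipes for the log-normal primitives, matching
# the standard heterogeneous-group setup: unit means, 10% dispersion.
DEFAULT_DISTS: dict[str, dict[str, tuple[float, float]]] = {
    "coordination": {"theta_pref": (1.0, 0.1), "c": (1.0, 0.1), "d": (1.0, 0.1)},
    "pgg_quadratic": {"c": (1.0, 0.1)},
    "cpr": {"c": (1.0, 0.1), "d": (1.0, 0.1)},
    "generic": {},
}

_DEFAULT_FIXED: dict[str, dict[str, float]] = {
    "coordination": {"b": 1.0},
    "pgg_quadratic": {"b": 40.0},
    "cpr": {"b": 10.0},
    "generic": {"D0": 0.0, "D1": 0.0, "D2": 0.0},
}


@dataclass(frozen=True)
class PopulationConfig:
    """Recipe for sampling one heterogeneous group.

    ``dists`` maps game-parameter names to (mean, sd) of a moment-matched
    log-normal; parameters in ``fixed`` are identical across agents.  The
    public-goods shares v_i always come from a broken stick.  ``epsilon``
    scales the four normative weights; ``weight_dist`` is the (mean, sd) of
    the base weights a1..a4 and of the raw belief-coefficient cells, whose
    rows are rescaled to ``belief_row_sum`` (< 1 keeps updates damped).
    """

    game: str = "coordination"
    n: int = 100
    epsilon: float = 1.0
    authority: Authority = field(default_factory=Authority)
    dists: Mapping[str, tuple[float, float]] | None = None
    fixed: Mapping[str, float] | None = None
    weight_dist: tuple[float, float] = (1.0, 0.1)
    belief_cell_dist: tuple[float, float] = (1.0, 0.1)
    belief_row_sum: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.n < 2:
            raise ValueError("group size n must be at least 2")
        if not 0.0 < self.belief_row_sum <= 1.0:
            raise ValueError("belief_row_sum must lie in (0, 1]")
        if self.game not in DEFAULT_DISTS:
            raise ValueError(f"unknown game {self.game!r}")

    def resolved_dists(self) -> dict[str, tuple[float, float]]:
        d = dict(DEFAULT_DISTS[self.game])
        if self.dists:
            d.update({k: tuple(v) for k, v in self.dists.items()})
        return d

    def resolved_fixed(self) -> dict[str, float]:
        f = dict(_DEFAULT_FIXED[self.game])
        if self.fixed:
            f.update(self.fixed)
        return f


@dataclass
class Group:
    """A sampled group: game, per-agent coefficients and derived theta."""

    game: GameSpec
    pc: PayoffCoeffs
    nw: NormWeights
    bw: BeliefWeights
    authority: Authority
    theta: np.ndarray
    base_weights: np.ndarray  # (n, 4) unscaled a1..a4
    epsilon: float

    @property
    def n(self) -> int:
        return self.game.n

    def to_dataframe(self):
        """One row per agent: game primitives, D/A coefficients and theta."""
        import pandas as pd

        n = self.n
        data = {
            "agent": np.arange(n),
            "D0": np.broadcast_to(self.pc.D0, (n,)),
            "D1": np.broadcast_to(self.pc.D1, (n,)),
            "D2": np.broadcast_to(self.pc.D2, (n,)),
            "A1": np.broadcast_to(self.nw.A1, (n,)),
            "A2": np.broadcast_to(self.nw.A2, (n,)),
            "A3": np.broadcast_to(self.nw.A3, (n,)),
            "A4": np.broadcast_to(self.nw.A4, (n,)),
            "theta": self.theta,
        }
        for i in range(3):
            for j in range(3):
                data[f"C{i + 1}{j + 1}"] = self.bw.C[:, i, j]
        return pd.DataFrame(data)


def _sample_game(cfg: PopulationConfig, rng: np.random.Generator) -> GameSpec:
    dists, fixed, n = cfg.resolved_dists(), cfg.resolved_fixed(), cfg.n

    def draw(name: str):
        if name in dists:
            mean, sd = dists[name]
            return sample_lognormal(mean, sd, n, rng)
        return float(fixed[name])

    if cfg.game == "coordination":
        params = CoordinationParams(b=draw("b"), c=draw("c"), d=draw("d"),
                                    theta_pref=draw("theta_pref"))
    elif cfg.game == "pgg_quadratic":
        params = PGGQuadParams(b=draw("b"), v=sample_broken_stick(n, rng), c=draw("c"))
    elif cfg.game == "cpr":
        params = CPRParams(b=draw("b"), d=draw("d"), c=draw("c"))
    else:
        params = GenericParams(D0=draw("D0"), D1=draw("D1"), D2=draw("D2"))
    return GameSpec(name=cfg.game, params=params, n=n)


def build_group(cfg: PopulationConfig, rng=None) -> Group:
    """Sample one full group: game primitives, normative and belief weights.

    Base weights a1..a4 are log-normal (``weight_dist``) and enter the utility
    as A_k = epsilon * a_k; with the authority off, A4 and the authority
    column of the belief coefficients are zeroed.  Raw belief cells are
    log-normal (``belief_cell_dist``) and each row is rescaled to sum to
    ``belief_row_sum``.
    """
    rng = _rng(cfg.seed if rng is None else rng)
    game = _sample_game(cfg, rng)
    pc = payoff_coeffs(game)

    wm, ws = cfg.weight_dist
    a = sample_lognormal(wm, ws, 4 * cfg.n, rng).reshape(cfg.n, 4)
    if not cfg.authority.active:
        a[:, 3] = 0.0
    A = cfg.epsilon * a
    nw = NormWeights(A1=A[:, 0], A2=A[:, 1], A3=A[:, 2], A4=A[:, 3])

    cm, cs = cfg.belief_cell_dist
    raw = sample_lognormal(cm, cs, 9 * cfg.n, rng).reshape(cfg.n, 3, 3)
    if not cfg.authority.active:
        raw[:, :, 2] = 0.0
    C = raw / raw.sum(axis=2, keepdims=True) * cfg.belief_row_sum
    bw = BeliefWeights(C)

    try:
        th = np.broadcast_to(theta(pc), (cfg.n,)).astype(float)
    except NonConcavePayoffError:
        # e.g. all-D-zero generic games: no material best response exists
        th = np.full(cfg.n, np.nan)
    return Group(game=game, pc=pc, nw=nw, bw=bw, authority=cfg.authority,
                 theta=th, base_weights=a, epsilon=cfg.epsilon)


def initial_states(n: int, seed, low: float = 0.0, high: float = 0.1) -> AgentState:
    """Initial x, y, x_exp, y_exp i.i.d. uniform on [low, high] per agent."""
    u = _rng(seed).uniform(low, high, size=(4, n))
    return AgentState(x=u[0], y=u[1], x_exp=u[2], y_exp=u[3])
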