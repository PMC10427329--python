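"""Named social-dilemma games: payoffs, marginal coefficients and EGT baselines.

Each game maps per-agent primitives to the linear-marginal coefficients
(D0, D1, D2) consumed by :mod:`normdyn.model_core`, writing the predicted
group effort as Z = x + (n-1)*x_exp (own action plus believed peers' mean).

coordination
    pi_i = b_i - c_i (x - theta_pref_i)^2 - d_i (x - x_exp)^2 :
    a personally preferred action plus a quadratic miscoordination cost.
pgg_quadratic
    pi_i = v_i * b * Z - c_i x^2 / 2 : public-goods production bZ shared in
    fixed slices v_i, quadratic personal cost of effort.
cpr
    pi_i = (x/Z)(bZ - d Z^2 / 2) - c_i x : common-pool extraction with
    diminishing group return and effort-proportional shares (Tullock-style).
generic
    explicit (D0, D1, D2) pass-through covering linear (D1 = D2 = 0) and
    quasi-linear (D2 = 0) payoffs without a named preset.

Parameters may be scalars or per-agent arrays of length n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .model_core import PayoffCoeffs, theta

__all__ = [
    "CoordinationParams",
    "PGGQuadParams",
    "CPRParams",
    "GenericParams",
    "GameSpec",
    "GAME_NAMES",
    "payoff_coeffs",
    "payoff_value",
    "nash_baseline",
    "social_optimum_cpr",
    "conformity_ratio",
]

GAME_NAMES = ("coordination", "pgg_quadratic", "cpr", "generic")


def _as_f(v):
    return np.asarray(v, dtype=float)


@dataclass(frozen=True)
class CoordinationParams:
    """b: max benefit; c: cost of deviating from the preferred action
    theta_pref; d: miscoordination cost against the peers' mean."""

    b: float | np.ndarray = 1.0
    c: float | np.ndarray = 1.0
    d: float | np.ndarray = 1.0
    theta_pref: float | np.ndarray = 1.0

    def __post_init__(self):
        if np.any(_as_f(self.c) <= 0):
            raise ValueError("c must be positive")
        if np.any(_as_f(self.d) < 0):
            raise ValueError("d must be non-negative")
        if np.any(_as_f(self.theta_pref) < 0):
            raise ValueError("theta_pref must be non-negative")


@dataclass(frozen=True)
class PGGQuadParams:
    """b: multiplier on total effort; v: agent's share of the group product
    (in [0,1]); c: quadratic personal cost coefficient."""

    b: float | np.ndarray = 40.0
    v: float | np.ndarray = 1.0 / 40.0
    c: float | np.ndarray = 1.0

    def __post_init__(self):
        if np.any(_as_f(self.b) <= 0) or np.any(_as_f(self.c) <= 0):
            raise ValueError("b and c must be positive")
        if np.any((_as_f(self.v) < 0) | (_as_f(self.v) > 1)):
            raise ValueError("shares v must lie in [0, 1]")


@dataclass(frozen=True)
class CPRParams:
    """b: linear return coefficient; d: diminishing-return coefficient in
    P = bZ - d Z^2 / 2; c: linear individual cost coefficient (b > c)."""

    b: float | np.ndarray = 10.0
    d: float | np.ndarray = 1.0
    c: float | np.ndarray = 1.0

    def __post_init__(self):
        if np.any(_as_f(self.d) <= 0):
            raise ValueError("d must be positive")
        if np.any(_as_f(self.c) < 0):
            raise ValueError("c must be non-negative")
        if np.any(_as_f(self.b) <= _as_f(self.c)):
            raise ValueError("require b > c (positive marginal surplus)")


@dataclass(frozen=True)
class GenericParams:
    """Explicit marginal-payoff coefficients; no named payoff function."""

    D0: float | np.ndarray = 0.0
    D1: float | np.ndarray = 0.0
    D2: float | np.ndarray = 0.0


GameParams = Union[CoordinationParams, PGGQuadParams, CPRParams, GenericParams]

_PARAM_TYPES = {
    "coordination": CoordinationParams,
    "pgg_quadratic": PGGQuadParams,
    "cpr": CPRParams,
    "generic": GenericParams,
}


@dataclass(frozen=True)
class GameSpec:
    """A named game with per-agent primitives and the group size n."""

    name: str
    params: GameParams
    n: int

    def __post_init__(self):
        if self.name not in GAME_NAMES:
            raise ValueError(f"unknown game {self.name!r}; expected one of {GAME_NAMES}")
        if not isinstance(self.params, _PARAM_TYPES[self.name]):
            raise TypeError(
                f"game {self.name!r} requires {_PARAM_TYPES[self.name].__name__}, "
                f"got {type(self.params).__name__}"
            )
        if self.n < 2:
            raise ValueError("group size n must be at least 2")


def _select(value, agent_index):
    v = _as_f(value)
    if agent_index is None or v.ndim == 0:
        return v if v.ndim else float(v)
    return float(v[agent_index])


def payoff_coeffs(game: GameSpec, agent_index: int | None = None) -> PayoffCoeffs:
    """Linear-marginal coefficients (D0, D1, D2) of one agent (or all, vectorised).

    coordination: (2 c theta_pref, 2 d, 2 (c + d))
    pgg_quadratic: (v b, 0, c)
    cpr: (b - c, -d (n - 1) / 2, d)   [D1 scales with the group size]
    generic: the explicit coefficients unchanged.
    """
    p, n = game.params, game.n
    if game.name == "coordination":
        c, d = _select(p.c, agent_index), _select(p.d, agent_index)
        tp = _select(p.theta_pref, agent_index)
        return PayoffCoeffs(D0=2.0 * c * tp, D1=2.0 * d, D2=2.0 * (c + d))
    if game.name == "pgg_quadratic":
        b, v, c = (_select(p.b, agent_index), _select(p.v, agent_index),
                   _select(p.c, agent_index))
        zero = np.zeros(np.broadcast(_as_f(v), _as_f(b), _as_f(c)).shape)
        return PayoffCoeffs(D0=v * b, D1=zero if zero.ndim else 0.0, D2=c)
    if game.name == "cpr":
        b, c, d = (_select(p.b, agent_index), _select(p.c, agent_index),
                   _select(p.d, agent_index))
        return PayoffCoeffs(D0=b - c, D1=-d * (n - 1) / 2.0, D2=d)
    return PayoffCoeffs(D0=_select(p.D0, agent_index), D1=_select(p.D1, agent_index),
                        D2=_select(p.D2, agent_index))


def payoff_value(game: GameSpec, agent_index: int | None, x, x_exp):
    """Literal game payoff at action x under predicted group effort Z = x + (n-1) x_exp.

    For the CPR game with Z = 0 (which requires x = 0) the product share is
    taken as the x -> 0 limit, giving payoff -c*x = 0.
    """
    p, n = game.params, game.n
    x, xe = _as_f(x), _as_f(x_exp)
    if game.name == "coordination":
        b, c = _select(p.b, agent_index), _select(p.c, agent_index)
        d, tp = _select(p.d, agent_index), _select(p.theta_pref, agent_index)
        return b - c * (x - tp) ** 2 - d * (x - xe) ** 2
    Z = x + (n - 1) * xe
    if game.name == "pgg_quadratic":
        b, v, c = (_select(p.b, agent_index), _select(p.v, agent_index),
                   _select(p.c, agent_index))
        return v * b * Z - c * x * x / 2.0
    if game.name == "cpr":
        b, c, d = (_select(p.b, agent_index), _select(p.c, agent_index),
                   _select(p.d, agent_index))
        with np.errstate(divide="ignore", invalid="ignore"):
            share = np.where(Z > 0, x / np.where(Z > 0, Z, 1.0), 0.0)
        return share * (b * Z - d * Z * Z / 2.0) - c * x
    pc = payoff_coeffs(game, agent_index)
    return _as_f(pc.D0) * x + _as_f(pc.D1) * xe * x - _as_f(pc.D2) * x * x / 2.0


def conformity_ratio(params: CoordinationParams):
    """Relative strength of conformity pressure r = d / (c + d), in [0, 1]."""
    c, d = _as_f(params.c), _as_f(params.d)
    if np.any(c + d == 0):
        raise ValueError("conformity ratio undefined when c = d = 0")
    return d / (c + d)


def _broadcast_all(n, *values):
    return [np.broadcast_to(_as_f(v), (n,)).astype(float) for v in values]


def nash_baseline(game: GameSpec) -> np.ndarray:
    """Per-agent Nash-equilibrium efforts of the material game (no normative terms).

    pgg_quadratic: x_i = theta_i = v_i b / c_i exactly (no strategic coupling).
    cpr with identical c and d: x = 2 (b - c) / (d (n + 1)); heterogeneous
    agents: the linear first-order-condition system is solved numerically.
    coordination: solves the linear best-reply system
    x_i = (1 - r_i) theta_pref_i + r_i * mean of the others' actions.
    """
    p, n = game.params, game.n
    if game.name == "pgg_quadratic":
        v, b, c = _broadcast_all(n, p.v, p.b, p.c)
        return v * b / c
    if game.name == "cpr":
        b, c, d = _broadcast_all(n, p.b, p.c, p.d)
        if np.ptp(c) == 0 and np.ptp(d) == 0 and np.ptp(b) == 0:
            return np.full(n, 2.0 * (b[0] - c[0]) / (d[0] * (n + 1)))
        # FOC for agent i, others at x_j: (b-c_i) - d_i x_i - (d_i/2)(S - x_i) = 0
        A = np.tile((d / 2.0)[:, None], (1, n))
        A[np.diag_indices(n)] = d
        rhs = b - c
        try:
            x = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
            raise ValueError("singular first-order-condition system") from exc
        _check_foc(A, x, rhs)
        return x
    if game.name == "coordination":
        tp, = _broadcast_all(n, p.theta_pref)
        r = np.broadcast_to(conformity_ratio(p), (n,)).astype(float)
        # x_i - r_i/(n-1) * sum_{j != i} x_j = (1 - r_i) theta_pref_i
        A = np.eye(n) - (r / (n - 1))[:, None] * (np.ones((n, n)) - np.eye(n))
        rhs = (1.0 - r) * tp
        try:
            x = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ValueError("singular best-reply system") from exc
        _check_foc(A, x, rhs)
        return x
    # generic: FOC D0 + D1 * mean_{-i}(x) - D2 x_i = 0
    D0, D1, D2 = _broadcast_all(n, p.D0, p.D1, p.D2)
    if np.any(D2 == 0):
        raise ValueError("generic Nash baseline undefined for D2 = 0 (linear payoff)")
    A = np.diag(D2) - (D1 / (n - 1))[:, None] * (np.ones((n, n)) - np.eye(n))
    try:
        x = np.linalg.solve(A, D0)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("singular first-order-condition system") from exc
    _check_foc(A, x, D0)
    return x


def _check_foc(A, x, rhs, tol=1e-10):
    resid = np.max(np.abs(A @ x - rhs)) / max(1.0, np.max(np.abs(rhs)))
    if resid > tol:  # pragma: no cover - solve is direct
        raise ValueError(f"first-order conditions not met (residual {resid:.2e})")


def social_optimum_cpr(params: CPRParams, n: int) -> float:
    """Symmetric per-agent effort maximising the total CPR group payoff.

    Total payoff bZ - d Z^2/2 - cZ is maximised at group effort
    Z_opt = (b - c)/d; split equally, x_opt = (b - c)/(d n).  The identical-
    agent Nash effort is 2n/(n+1) times larger than x_opt.
    """
    b = float(np.mean(_as_f(params.b)))
    c = float(np.mean(_as_f(params.c)))
    d = float(np.mean(_as_f(params.d)))
    return (b - c) / (d * n)
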