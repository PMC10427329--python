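"""Single-agent primitives of the norm-dynamics model.

An agent facing a repeated social dilemma carries four state variables, all
non-negative reals:

``x``
    the action actually taken (effort, contribution, harvest level, ...);
``y``
    the attitude, i.e. the agent's personal norm about the appropriate action;
``x_exp`` (written x-tilde in the field)
    the empirical expectation: the believed average action of the peers;
``y_exp`` (y-tilde)
    the normative expectation: the believed average attitude of the peers
    (a second-order belief).

The agent chooses its action by myopic best response to a subjective utility

    u(x) = pi(x, x_exp) - A1 (x - y)^2 - A2 (x - y_exp)^2
                        - A3 (x - x_exp)^2 - A4 (x - G)^2

where ``pi`` is the material payoff, the ``A`` terms are psychic costs of
cognitive dissonance, peer disapproval, non-conformity with peers' actions and
non-conformity with an external authority promoting a standard action ``G``.
For the linear/quadratic games handled here the marginal material payoff is
linear,

    d(pi)/dx = D0 + D1 * x_exp - D2 * x,

so the whole utility is a concave quadratic and the best response is closed
form.  After acting and observing the peers' mean action ``X``, the agent
revises attitude and beliefs by a damped linear move (cognitive dissonance,
social projection, the logic constraint, learning from peers, authority pull),
parameterised by a non-negative 3x3 coefficient matrix ``C``.

All operations accept scalars or NumPy arrays (one entry per agent) and
broadcast; the group-level dynamics in :mod:`normdyn.dynamics` call them on
whole populations at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "PayoffCoeffs",
    "NormWeights",
    "BeliefWeights",
    "AgentState",
    "Authority",
    "BestResponseCoeffs",
    "NormalizedWeights",
    "NonConcavePayoffError",
    "marginal_payoff",
    "material_payoff",
    "theta",
    "utility",
    "best_response",
    "best_response_coeffs",
    "update_beliefs",
    "normalized_weights",
]


class NonConcavePayoffError(ValueError):
    """Raised when a degenerate/non-concave objective makes a maximiser undefined."""


def _as_f(v):
    return np.asarray(v, dtype=float)


@dataclass(frozen=True)
class PayoffCoeffs:
    """Coefficients of the linear marginal material payoff.

    ``marginal = D0 + D1 * x_exp - D2 * x``.  ``D1`` may be negative (rivalrous
    games); ``D2 >= 0`` with ``D2 = 0`` allowed for the linear/quasi-linear
    games reachable through the generic interface.
    """

    D0: float | np.ndarray
    D1: float | np.ndarray
    D2: float | np.ndarray

    def __post_init__(self):
        if np.any(_as_f(self.D2) < 0):
            raise ValueError("D2 must be non-negative")


@dataclass(frozen=True)
class NormWeights:
    """Non-negative weights of the four normative penalty terms in the utility.

    A1: cognitive dissonance, A2: disapproval by peers, A3: conformity with
    peers' actions, A4: conformity with the external authority.
    """

    A1: float | np.ndarray = 0.0
    A2: float | np.ndarray = 0.0
    A3: float | np.ndarray = 0.0
    A4: float | np.ndarray = 0.0

    def __post_init__(self):
        for name in ("A1", "A2", "A3", "A4"):
            if np.any(_as_f(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")

    def scaled(self, epsilon: float) -> "NormWeights":
        """All four weights multiplied by a common factor (the epsilon dial)."""
        return NormWeights(
            A1=self.A1 * epsilon, A2=self.A2 * epsilon,
            A3=self.A3 * epsilon, A4=self.A4 * epsilon,
        )


@dataclass(frozen=True)
class Authority:
    """External authority promoting a standard action G; inactive => no effect.

    When inactive, downstream code sees A4 = 0 and a zero authority column in
    the belief-update coefficients (enforced by :func:`gate`).
    """

    active: bool = False
    G: float = 0.0

    def __post_init__(self):
        if self.G < 0:
            raise ValueError("G must be non-negative")

    def gate(self, A4):
        """Return ``(effective_A4, effective_G)``: zeros when inactive."""
        if self.active:
            return A4, self.G
        return np.zeros_like(_as_f(A4)) if np.ndim(A4) else 0.0, 0.0


@dataclass(frozen=True)
class BeliefWeights:
    """3x3 non-negative coefficients of the attitude/belief recurrences.

    Rows update (y, y_exp, x_exp) in that order; columns weigh the pull
    towards (own-state channel, observed peers' mean X, authority standard G):

        row 1 (y):     C11 cognitive dissonance, C12 conformity w/ peers, C13 authority
        row 2 (y_exp): C21 social projection,    C22 learning about others, C23 authority
        row 3 (x_exp): C31 logic constraint,     C32 learning about others, C33 authority

    Each row sum must be <= 1 so the update is a damped convex move and the
    state stays bounded.  ``C`` may be shape (3, 3) or (n, 3, 3).
    """

    C: np.ndarray

    def __post_init__(self):
        C = _as_f(self.C)
        if C.shape[-2:] != (3, 3):
            raise ValueError("C must have trailing shape (3, 3)")
        if np.any(C < 0):
            raise ValueError("belief coefficients must be non-negative")
        if np.any(C.sum(axis=-1) > 1 + 1e-12):
            raise ValueError("each row of C must sum to at most 1 (damped update)")
        object.__setattr__(self, "C", C)

    def without_authority(self) -> "BeliefWeights":
        C = self.C.copy()
        C[..., :, 2] = 0.0
        return BeliefWeights(C)


@dataclass
class AgentState:
    """Current action and attitude/belief variables; all components >= 0."""

    x: float | np.ndarray
    y: float | np.ndarray
    x_exp: float | np.ndarray
    y_exp: float | np.ndarray

    def __post_init__(self):
        for name in ("x", "y", "x_exp", "y_exp"):
            if np.any(_as_f(getattr(self, name)) < 0):
                raise ValueError(f"state component {name} must be non-negative")

    def copy(self) -> "AgentState":
        return AgentState(
            np.array(self.x, dtype=float, copy=True),
            np.array(self.y, dtype=float, copy=True),
            np.array(self.x_exp, dtype=float, copy=True),
            np.array(self.y_exp, dtype=float, copy=True),
        )


class BestResponseCoeffs(NamedTuple):
    """Rescaled coefficients of the closed-form best response.

    ``x* = max(0, B0 + B1*x_exp + B2*y + B3*y_exp + B4*G)``.
    """

    B0: float | np.ndarray
    B1: float | np.ndarray
    B2: float | np.ndarray
    B3: float | np.ndarray
    B4: float | np.ndarray


class NormalizedWeights(NamedTuple):
    """Row-normalised belief weights: alpha (cognitive), beta (peers), gamma (authority).

    Each is the 3-vector (or (n, 3) array) of per-row shares; rows with zero
    sum are flagged with NaN (a frozen belief channel has no defined shares).
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray


def marginal_payoff(pc: PayoffCoeffs, x, x_exp):
    """Marginal material payoff d(pi)/dx = D0 + D1*x_exp - D2*x."""
    return _as_f(pc.D0) + _as_f(pc.D1) * _as_f(x_exp) - _as_f(pc.D2) * _as_f(x)


def material_payoff(pc: PayoffCoeffs, x, x_exp):
    """Quadratic antiderivative of the marginal payoff in x (integration constant 0).

    pi = D0*x + D1*x_exp*x - D2*x^2/2.  Only differences in x are ever used,
    so the constant of integration is immaterial.
    """
    x = _as_f(x)
    return _as_f(pc.D0) * x + _as_f(pc.D1) * _as_f(x_exp) * x - _as_f(pc.D2) * x * x / 2.0


def theta(pc: PayoffCoeffs):
    """Self-consistent material best response theta = D0 / (D2 - D1).

    The action solving ``marginal_payoff(pc, x, x) = 0``: the best response of
    an agent who believes peers will mirror its own action.  In the named
    games theta is a benefit-to-cost summary and often the Nash effort.
    """
    denom = _as_f(pc.D2) - _as_f(pc.D1)
    if np.any(denom <= 0):
        raise NonConcavePayoffError(
            "theta undefined: requires D2 - D1 > 0 (self-consistent payoff concave)"
        )
    return _as_f(pc.D0) / denom


def utility(pc: PayoffCoeffs, nw: NormWeights, auth: Authority, st: AgentState, x):
    """Subjective utility at action x given the current state (beliefs fixed)."""
    x = _as_f(x)
    A4, G = auth.gate(nw.A4)
    u = material_payoff(pc, x, st.x_exp)
    u = u - _as_f(nw.A1) * (x - _as_f(st.y)) ** 2
    u = u - _as_f(nw.A2) * (x - _as_f(st.y_exp)) ** 2
    u = u - _as_f(nw.A3) * (x - _as_f(st.x_exp)) ** 2
    u = u - _as_f(A4) * (x - G) ** 2
    return u


def _br_parts(pc: PayoffCoeffs, nw: NormWeights, auth: Authority):
    A4, G = auth.gate(nw.A4)
    den = _as_f(pc.D2) + 2.0 * (_as_f(nw.A1) + _as_f(nw.A2) + _as_f(nw.A3) + _as_f(A4))
    return A4, G, den


def best_response_coeffs(pc: PayoffCoeffs, nw: NormWeights, auth: Authority) -> BestResponseCoeffs:
    """The rescaled (B0..B4) coefficients implied by the quadratic utility."""
    A4, _, den = _br_parts(pc, nw, auth)
    if np.any(den <= 0):
        raise NonConcavePayoffError("utility not strictly concave: D2 + 2*sum(A) must be > 0")
    return BestResponseCoeffs(
        B0=_as_f(pc.D0) / den,
        B1=(_as_f(pc.D1) + 2.0 * _as_f(nw.A3)) / den,
        B2=2.0 * _as_f(nw.A1) / den,
        B3=2.0 * _as_f(nw.A2) / den,
        B4=2.0 * _as_f(A4) / den,
    )


def best_response(pc: PayoffCoeffs, nw: NormWeights, auth: Authority, st: AgentState,
                  clip: bool = True):
    """Utility-maximising action given the current attitude and beliefs.

    Closed form: the unconstrained maximiser of the concave quadratic utility,
    clipped at zero (actions are non-negative).  ``clip=False`` returns the
    raw stationary point, used by the linear fixed-point solver.
    """
    A4, G, den = _br_parts(pc, nw, auth)
    if np.any(den <= 0):
        raise NonConcavePayoffError("utility not strictly concave: D2 + 2*sum(A) must be > 0")
    num = (
        _as_f(pc.D0)
        + (_as_f(pc.D1) + 2.0 * _as_f(nw.A3)) * _as_f(st.x_exp)
        + 2.0 * _as_f(nw.A1) * _as_f(st.y)
        + 2.0 * _as_f(nw.A2) * _as_f(st.y_exp)
        + 2.0 * _as_f(A4) * G
    )
    x = num / den
    return np.maximum(0.0, x) if clip else x


def update_beliefs(bw: BeliefWeights, st: AgentState, X_obs, auth: Authority,
                   clip: bool = True) -> AgentState:
    """One damped linear revision of attitude and beliefs after observing X.

    y'     = y     + C11 (x - y)         + C12 (X - y)     + C13 (G - y)
    y_exp' = y_exp + C21 (y - y_exp)     + C22 (X - y_exp) + C23 (G - y_exp)
    x_exp' = x_exp + C31 (y_exp - x_exp) + C32 (X - x_exp) + C33 (G - x_exp)

    The action x is unchanged by this operation; updated components are
    clipped at 0.  When the authority is inactive the authority column is
    ignored (treated as zero).
    """
    C = bw.C if auth.active else bw.without_authority().C
    G = auth.G if auth.active else 0.0
    X = _as_f(X_obs)
    x, y, ye, xe = _as_f(st.x), _as_f(st.y), _as_f(st.y_exp), _as_f(st.x_exp)
    y2 = y + C[..., 0, 0] * (x - y) + C[..., 0, 1] * (X - y) + C[..., 0, 2] * (G - y)
    ye2 = ye + C[..., 1, 0] * (y - ye) + C[..., 1, 1] * (X - ye) + C[..., 1, 2] * (G - ye)
    xe2 = xe + C[..., 2, 0] * (ye - xe) + C[..., 2, 1] * (X - xe) + C[..., 2, 2] * (G - xe)
    if clip:
        y2, ye2, xe2 = np.maximum(0.0, y2), np.maximum(0.0, ye2), np.maximum(0.0, xe2)
        return replace(st, y=y2, y_exp=ye2, x_exp=xe2)
    # unclipped variant (linear solver plumbing): skip the non-negativity check
    out = AgentState.__new__(AgentState)
    out.x, out.y, out.y_exp, out.x_exp = st.x, y2, ye2, xe2
    return out


def normalized_weights(bw: BeliefWeights) -> NormalizedWeights:
    """Per-row shares alpha (cognitive), beta (peer learning), gamma (authority).

    alpha_i + beta_i + gamma_i = 1 for every row with a positive sum; rows
    summing to zero (frozen channels) are flagged with NaN and a warning
    rather than an error.
    """
    C = bw.C
    rowsum = C.sum(axis=-1)
    zero = rowsum == 0
    if np.any(zero):
        warnings.warn("zero-sum belief rows: normalized weights undefined (NaN)",
                      stacklevel=2)
    safe = np.where(zero, np.nan, rowsum)
    return NormalizedWeights(
        alpha=C[..., 0] / safe, beta=C[..., 1] / safe, gamma=C[..., 2] / safe
    )
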