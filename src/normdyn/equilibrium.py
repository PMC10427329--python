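"""Exact deterministic fixed points of the coupled action/belief system.

With noise off and every agent revising each step, the map

    (y, y_exp, x_exp)  ->  best responses x  ->  observed peer means X
                       ->  updated (y, y_exp, x_exp)

is affine in the stacked 3n-vector of attitudes and beliefs (as long as the
non-negativity clips are inactive, which holds at interior equilibria).  The
solver assembles the affine map exactly — including the leave-self-out
coupling through X — checks that its linear part is a contraction (spectral
radius < 1), and solves the 3n-dimensional stationarity system directly.
Actions are recovered through the closed-form best response.

Two regimes admit closed-form equilibria and are reproduced exactly: a
homogeneous-theta group without authority converges to every variable equal
to theta, and a group with no material payoffs under an authority promoting
G converges to every variable equal to G.  With heterogeneous material
payoffs and no authority, the group-mean action approximately equals the
population mean of theta (a large-n result); the exact solver quantifies the
finite-n gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_core import AgentState, best_response, update_beliefs
from .population import Group

__all__ = ["EquilibriumReport", "NonContractiveError", "exact_fixed_point",
           "predicted_mean_action", "regime_classify"]

_RESIDUAL_TOL = 1e-10


class NonContractiveError(RuntimeError):
    """The deterministic dynamics are not a contraction: no unique stable fixed point."""


@dataclass
class EquilibriumReport:
    """Fixed point of the noise-free dynamics plus diagnostics."""

    x: np.ndarray
    y: np.ndarray
    x_exp: np.ndarray
    y_exp: np.ndarray
    regime: str
    theta_mean: float
    spectral_radius: float
    residual: float
    interior: bool  # True if no component of the fixed point is negative

    @property
    def means(self) -> dict[str, float]:
        return {
            "x": float(self.x.mean()),
            "y": float(self.y.mean()),
            "x_exp": float(self.x_exp.mean()),
            "y_exp": float(self.y_exp.mean()),
        }

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "theta_mean": self.theta_mean,
            "spectral_radius": self.spectral_radius,
            "residual": self.residual,
            "interior": self.interior,
            "means": self.means,
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "x_exp": self.x_exp.tolist(),
            "y_exp": self.y_exp.tolist(),
        }


def _affine_apply(group: Group, s: np.ndarray) -> np.ndarray:
    """One noise-free all-revising step on the stacked (y, y_exp, x_exp) vector,
    with all clips disabled so the map is exactly affine."""
    n = group.n
    st = AgentState.__new__(AgentState)  # bypass non-negativity check: raw affine map
    st.y, st.y_exp, st.x_exp = s[:n], s[n:2 * n], s[2 * n:]
    st.x = np.zeros(n)
    x = best_response(group.pc, group.nw, group.authority, st, clip=False)
    X = (x.sum() - x) / (n - 1)
    st.x = x
    new = update_beliefs(group.bw, st, X, group.authority, clip=False)
    return np.concatenate([new.y, new.y_exp, new.x_exp])


def exact_fixed_point(group: Group) -> EquilibriumReport:
    """Solve the 3n-dimensional linear stationarity system directly.

    Raises :class:`NonContractiveError` when the spectral radius of the
    linear part is >= 1 (the deterministic dynamics would not converge).
    The certified residual of the returned point is below 1e-10.
    """
    n = group.n
    dim = 3 * n
    b = _affine_apply(group, np.zeros(dim))
    M = np.empty((dim, dim))
    eye = np.eye(dim)
    for j in range(dim):
        M[:, j] = _affine_apply(group, eye[j]) - b
    rho = float(np.max(np.abs(np.linalg.eigvals(M))))
    if rho >= 1.0:
        raise NonContractiveError(
            f"spectral radius {rho:.6f} >= 1: deterministic dynamics not contractive"
        )
    try:
        s = np.linalg.solve(np.eye(dim) - M, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rho<1 implies invertible
        raise NonContractiveError("singular stationarity system") from exc
    scale = max(1.0, float(np.max(np.abs(s))))
    residual = float(np.max(np.abs(_affine_apply(group, s) - s))) / scale
    if residual > _RESIDUAL_TOL:  # pragma: no cover - direct solve
        raise RuntimeError(f"fixed-point residual {residual:.2e} exceeds tolerance")

    st = AgentState.__new__(AgentState)
    st.y, st.y_exp, st.x_exp = s[:n], s[n:2 * n], s[2 * n:]
    st.x = np.zeros(n)
    x = best_response(group.pc, group.nw, group.authority, st, clip=False)
    interior = bool(np.all(x >= 0) and np.all(s >= 0))
    if not interior:
        warnings.warn("fixed point has negative components; clipped stochastic "
                      "dynamics may settle elsewhere", stacklevel=2)
    theta_mean = float(np.nanmean(group.theta)) if np.any(np.isfinite(group.theta)) \
        else float("nan")
    return EquilibriumReport(
        x=x, y=s[:n].copy(), x_exp=s[2 * n:].copy(), y_exp=s[n:2 * n].copy(),
        regime=regime_classify(group), theta_mean=theta_mean,
        spectral_radius=rho, residual=residual, interior=interior,
    )


def predicted_mean_action(group: Group) -> float:
    """Closed-form predicted equilibrium group-mean action: mean of theta.

    Valid without an external authority (large-n result); with the authority
    on, the prediction does not apply and a warning is issued.
    """
    if group.authority.active:
        warnings.warn("mean-action = mean(theta) prediction assumes no external "
                      "authority; result is the no-authority baseline", stacklevel=2)
    return float(np.mean(group.theta))


def regime_classify(group: Group, tol: float = 1e-12) -> str:
    """Label the closed-form regime an instance falls into.

    'authority_only': no material payoffs, authority on (fixed point = G);
    'homogeneous': no authority, identical theta (fixed point = theta);
    'heterogeneous_no_authority': no authority, theta varies (mean ~ theta-bar);
    'general': everything else.
    """
    D_zero = (np.all(np.abs(np.asarray(group.pc.D0, dtype=float)) <= tol)
              and np.all(np.abs(np.asarray(group.pc.D1, dtype=float)) <= tol)
              and np.all(np.abs(np.asarray(group.pc.D2, dtype=float)) <= tol))
    if group.authority.active:
        return "authority_only" if D_zero else "general"
    th = group.theta
    if np.all(np.isfinite(th)) and np.ptp(th) <= tol:
        return "homogeneous"
    return "heterogeneous_no_authority"
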