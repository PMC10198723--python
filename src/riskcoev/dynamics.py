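"""Coupled strategy-risk vector fields on the unit square.

The cooperator frequency x follows replicator dynamics sped up by 1/eps,
while the risk of collective failure r evolves under a feedback law driven
by the strategy distribution:

    eps * dx/dt = x (1-x) [Gamma(x) r b - c]
    dr/dt       = r (1-r) K(x)

with K(x) = u(1-x) - x for linear feedback (risk grows with defection at
rate u, shrinks with cooperation at unit rate) and K(x) = B(x - T) for
sigmoid ("exponential") feedback, where

    B(xi) = 1/(1 + e^{beta xi}) - 1/(1 + e^{-beta xi}) = -tanh(beta xi / 2),

so the risk falls whenever cooperation exceeds the threshold T and rises
otherwise, with steepness beta. Both components vanish on their respective
boundaries, so [0,1]^2 is forward invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .game import GameParams, gamma, gamma_prime, payoff_difference

__all__ = ["FeedbackSpec", "CoupledSystem", "sigmoid_B", "risk_rate",
           "system_rhs"]

VARIANTS = ("linear", "exponential", "custom")


def sigmoid_B(xi, beta: float):
    """Sigmoid feedback kernel B(xi) = 1/(1+e^{beta xi}) - 1/(1+e^{-beta xi}).

    Evaluated as -tanh(beta*xi/2), which is algebraically identical and
    overflow-safe for arbitrarily large beta*xi (the step-like beta -> inf
    regime). Odd and decreasing in xi; identically zero for beta = 0.
    """
    if beta < 0:
        raise ValueError(f"steepness beta must be >= 0 (got {beta})")
    out = -np.tanh(0.5 * beta * np.asarray(xi, dtype=float))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FeedbackSpec:
    """Risk-update law: how the strategy distribution moves the risk.

    variant="linear"       dr/dt = r(1-r)[u(1-x) - x], u > 0
    variant="exponential"  dr/dt = r(1-r) B(x - T; beta), 0 < T < 1, beta >= 0
    variant="custom"       dr/dt = func(x, r) for an arbitrary callable
                           (no analytic equilibrium support)
    """

    variant: str
    u: Optional[float] = None
    T: Optional[float] = None
    beta: Optional[float] = None
    func: Optional[Callable[[float, float], float]] = field(
        default=None, compare=False)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"feedback variant must be one of {VARIANTS} "
                             f"(got {self.variant!r})")
        if self.variant == "linear":
            if self.u is None or not self.u > 0:
                raise ValueError(f"linear feedback requires rate u > 0 "
                                 f"(got {self.u})")
        elif self.variant == "exponential":
            if self.T is None or not 0 < self.T < 1:
                raise ValueError(f"exponential feedback requires threshold "
                                 f"0 < T < 1 (got {self.T})")
            if self.beta is None or self.beta < 0:
                raise ValueError(f"exponential feedback requires steepness "
                                 f"beta >= 0 (got {self.beta})")
        else:
            if not callable(self.func):
                raise ValueError("custom feedback requires a callable "
                                 "func(x, r) -> dr/dt")

    @property
    def is_static(self) -> bool:
        """True when the strategies cannot move the risk (beta = 0)."""
        return self.variant == "exponential" and self.beta == 0

    def kernel(self, x):
        """Strategy-dependent factor K(x) of dr/dt = r(1-r)K(x)."""
        if self.variant == "linear":
            return self.u * (1 - np.asarray(x, dtype=float)) - x
        if self.variant == "exponential":
            return sigmoid_B(np.asarray(x, dtype=float) - self.T, self.beta)
        raise ValueError("custom feedback has no separable kernel")

    def kernel_prime(self, x):
        """dK/dx, analytic for the linear and exponential variants."""
        if self.variant == "linear":
            return -(self.u + 1.0) * np.ones_like(np.asarray(x, dtype=float))
        if self.variant == "exponential":
            t = np.tanh(0.5 * self.beta * (np.asarray(x, dtype=float) - self.T))
            return -0.5 * self.beta * (1.0 - t * t)
        raise ValueError("custom feedback has no analytic kernel derivative")


def linear_feedback(u: float) -> FeedbackSpec:
    """Linear risk feedback with defection-driven enhancement rate u."""
    return FeedbackSpec(variant="linear", u=u)


def exponential_feedback(T: float, beta: float = 10.0) -> FeedbackSpec:
    """Sigmoid risk feedback with cooperation threshold T and steepness beta."""
    return FeedbackSpec(variant="exponential", T=T, beta=beta)


@dataclass(frozen=True)
class CoupledSystem:
    """The planar coevolutionary system: game + feedback + timescale ratio.

    eps is the relative speed of strategy updating; 0 < eps << 1 means
    strategies evolve much faster than the risk. eps rescales dx/dt only,
    so the fixed-point set is independent of it.
    """

    game: GameParams
    feedback: FeedbackSpec
    eps: float = 0.1

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValueError(f"feedback speed eps must be > 0 (got {self.eps})")

    def rhs(self, x: float, r: float) -> tuple[float, float]:
        return system_rhs(x, r, self)

    def rhs_vec(self, t, state):
        """solve_ivp-compatible signature."""
        return system_rhs(state[0], state[1], self)


def risk_rate(x: float, r: float, feedback: FeedbackSpec) -> float:
    """dr/dt under the given feedback law.

    The logistic factor r(1-r) pins the risk inside [0,1]: the rate is zero
    whenever r is 0 or 1 regardless of the strategy distribution.
    """
    if feedback.variant == "custom":
        return float(feedback.func(x, r))
    return float(r * (1 - r) * feedback.kernel(x))


def system_rhs(x: float, r: float, system: CoupledSystem) -> tuple[float, float]:
    """(dx/dt, dr/dt) of the coupled system at state (x, r).

    dx/dt = x(1-x)[Gamma(x) r b - c] / eps and dr/dt = risk_rate(x, r).
    Time is measured in units of the risk equation; eps divides the
    replicator term.
    """
    dx = x * (1 - x) * payoff_difference(x, r, system.game) / system.eps
    dr = risk_rate(x, r, system.feedback)
    return dx, dr


def jacobian(system: CoupledSystem, point) -> np.ndarray:
    """Analytic 2x2 Jacobian of the coupled vector field at (x, r).

    J11 = [(1-2x)(Gamma(x) r b - c) + x(1-x) Gamma'(x) r b] / eps
    J12 = x(1-x) Gamma(x) b / eps
    J21 = r(1-r) K'(x)
    J22 = (1-2r) K(x)

    For custom feedback the risk row falls back to central finite
    differences (step 1e-6).
    """
    x, r = float(point[0]), float(point[1])
    g = system.game
    gam = gamma(x, g)
    j11 = ((1 - 2 * x) * (gam * r * g.b - g.c)
           + x * (1 - x) * gamma_prime(x, g) * r * g.b) / system.eps
    j12 = x * (1 - x) * gam * g.b / system.eps
    fb = system.feedback
    if fb.variant == "custom":
        h = 1e-6
        j21 = (fb.func(x + h, r) - fb.func(x - h, r)) / (2 * h)
        j22 = (fb.func(x, r + h) - fb.func(x, r - h)) / (2 * h)
    else:
        j21 = r * (1 - r) * fb.kernel_prime(x)
        j22 = (1 - 2 * r) * fb.kernel(x)
    return np.array([[j11, j12], [j21, j22]], dtype=float)
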