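"""Threshold public-goods game (collective-risk social dilemma).

A group of ``N`` players each holds an endowment ``b``. Cooperators pay a
cost ``c`` into a common pool; if at least ``M`` group members cooperate the
collective target is met and everyone keeps their remaining endowment.
Otherwise every player loses the remaining endowment with probability ``r``
(the risk of collective failure).

This module provides the one-shot payoffs, the exact binomial average
payoffs in an infinite well-mixed population, and the closed-form gradient
of selection built on the pivotality kernel

    Gamma(x) = C(N-1, M-1) * x**(M-1) * (1-x)**(N-M),

the probability that a focal player finds exactly ``M-1`` cooperators among
its ``N-1`` co-players, i.e. that its own contribution is pivotal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GameParams",
    "heaviside",
    "payoff_cooperator",
    "payoff_defector",
    "gamma",
    "gamma_prime",
    "payoff_difference",
    "average_payoffs",
]

# Above this group size the direct power form of Gamma can underflow/overflow;
# evaluate through logs instead (never reached for the N used in practice).
_LOGSPACE_N = 50


@dataclass(frozen=True)
class GameParams:
    """Static parameters of the collective-risk game.

    Parameters
    ----------
    N : int
        Group size, at least 2.
    M : int
        Cooperator threshold required to avert collective failure; must
        satisfy 1 < M < N.
    b : float
        Initial endowment of every player (payoff units), positive.
    c : float
        Cost of cooperation, 0 < c < b. A cost c >= b would make defection
        strictly dominant at every composition and risk level, so it is
        rejected at construction.
    """

    N: int
    M: int
    b: float = 1.0
    c: float = 0.1

    def __post_init__(self) -> None:
        if not float(self.N).is_integer() or not float(self.M).is_integer():
            raise ValueError("N and M must be integers "
                             f"(got N={self.N!r}, M={self.M!r})")
        object.__setattr__(self, "N", int(self.N))
        object.__setattr__(self, "M", int(self.M))
        if self.N < 2:
            raise ValueError(f"group size N must be >= 2 (got {self.N})")
        if not (1 < self.M < self.N):
            raise ValueError(f"threshold M must satisfy 1 < M < N "
                             f"(got M={self.M}, N={self.N})")
        if not (self.b > 0):
            raise ValueError(f"endowment b must be positive (got {self.b})")
        if not (0 < self.c < self.b):
            raise ValueError(f"cost c must satisfy 0 < c < b "
                             f"(got c={self.c}, b={self.b})")

    @property
    def gamma_mode(self) -> float:
        """Location (M-1)/(N-1) of the maximum of the pivotality kernel."""
        return (self.M - 1) / (self.N - 1)

    @property
    def gamma_max(self) -> float:
        """Peak value Gamma((M-1)/(N-1)) of the pivotality kernel."""
        return gamma(self.gamma_mode, self)


def heaviside(z: float) -> int:
    """Step function with the right-continuous convention theta(0) = 1."""
    if not math.isfinite(z):
        raise ValueError(f"heaviside requires finite input (got {z})")
    return 0 if z < 0 else 1


def _check_jc(jC: int, params: GameParams) -> int:
    if not float(jC).is_integer():
        raise ValueError(f"jC must be an integer count (got {jC!r})")
    jC = int(jC)
    if not 0 <= jC <= params.N - 1:
        raise ValueError(f"jC must lie in [0, N-1] = [0, {params.N - 1}] "
                         f"(got {jC})")
    return jC


def payoff_cooperator(jC: int, r: float, params: GameParams) -> float:
    """Payoff of a cooperator with ``jC`` cooperating co-players at risk ``r``.

    b - c when the group (including the focal player) meets the threshold,
    (1-r)b - c otherwise.
    """
    jC = _check_jc(jC, params)
    met = heaviside(jC + 1 - params.M)
    return params.b * met + (1 - r) * params.b * (1 - met) - params.c


def payoff_defector(jC: int, r: float, params: GameParams) -> float:
    """Payoff of a defector with ``jC`` cooperating co-players at risk ``r``."""
    jC = _check_jc(jC, params)
    met = heaviside(jC - params.M)
    return params.b * met + (1 - r) * params.b * (1 - met)


def gamma(x, params: GameParams):
    """Pivotality kernel C(N-1, M-1) x^(M-1) (1-x)^(N-M).

    Vanishes at both ends of [0, 1] and peaks at x = (M-1)/(N-1). Accepts
    scalars or arrays.
    """
    N, M = params.N, params.M
    coeff = math.comb(N - 1, M - 1)
    x = np.asarray(x, dtype=float)
    if N > _LOGSPACE_N:
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = (math.log(coeff)
                    + (M - 1) * np.log(x) + (N - M) * np.log1p(-x))
        out = np.where((x > 0) & (x < 1), np.exp(logs), 0.0)
    else:
        out = coeff * x ** (M - 1) * (1 - x) ** (N - M)
    return out if out.ndim else float(out)


def gamma_prime(x, params: GameParams):
    """Analytic derivative of the pivotality kernel.

    Gamma'(x) = C(N-1,M-1) x^(M-2) (1-x)^(N-M-1) [(M-1)(1-x) - (N-M)x].
    The exponents M-2 and N-M-1 are non-negative for valid parameters.
    """
    N, M = params.N, params.M
    coeff = math.comb(N - 1, M - 1)
    x = np.asarray(x, dtype=float)
    out = (coeff * x ** (M - 2) * (1 - x) ** (N - M - 1)
           * ((M - 1) * (1 - x) - (N - M) * x))
    return out if out.ndim else float(out)


def payoff_difference(x: float, r: float, params: GameParams) -> float:
    """Closed-form advantage of cooperation, fC - fD = Gamma(x) r b - c.

    Equals the difference of the exact binomial average payoffs: the payoffs
    of a cooperator and a defector differ by rb - c at the pivotal
    composition jC = M-1 and by -c everywhere else, and the pivotal
    composition has probability Gamma(x).
    """
    return gamma(x, params) * r * params.b - params.c


def average_payoffs(x: float, r: float, params: GameParams) -> tuple[float, float]:
    """Exact average payoffs (fC, fD) by binomial enumeration.

    The number of cooperating co-players is Binomial(N-1, x); the payoffs of
    each composition are weighted by its probability mass. This is the
    brute-force oracle for :func:`payoff_difference`.
    """
    N = params.N
    jc = np.arange(N)
    pmf = stats.binom.pmf(jc, N - 1, x)
    fC = float(sum(p * payoff_cooperator(j, r, params)
                   for j, p in zip(jc, pmf)))
    fD = float(sum(p * payoff_defector(j, r, params)
                   for j, p in zip(jc, pmf)))
    return fC, fD
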