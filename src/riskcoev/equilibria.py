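"""Fixed points, stability, Hopf bifurcations and parameter regions.

Both feedback variants share the same fixed-point skeleton:

* the four corners (0,0), (0,1), (1,0), (1,1) of the unit square;
* up to two boundary points (x1*, 1) and (x2*, 1) where x1* <= x2* solve
  Gamma(x) b = c (the replicator null cline at maximal risk);
* at most one interior point where the risk kernel K(x) vanishes:
  (u/(1+u), r*) with r* = c / (Gamma(u/(1+u)) b) for linear feedback,
  (T, r_bar) with r_bar = c / (Gamma(T) b) for sigmoid feedback,
  existing only while the required risk stays strictly below 1.

At the interior point the Jacobian has J22 = 0 and J12 > 0 > J21, so its
trace is J11, whose sign is the sign of Gamma'(x_int). The trace crosses
zero exactly when the interior x sits at the mode (M-1)/(N-1) of the
pivotality kernel, giving the closed-form Hopf thresholds

    u_c = (M-1)/(N-M)   (linear)      T_c = (M-1)/(N-1)   (sigmoid).

The first Lyapunov coefficient at the threshold decides the criticality of
the bifurcation (negative -> supercritical, stable limit cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .dynamics import CoupledSystem, FeedbackSpec, jacobian, system_rhs
from .game import GameParams, gamma, gamma_prime

__all__ = [
    "FixedPoint",
    "RegionLabel",
    "find_threshold_roots",
    "interior_fixed_point",
    "enumerate_fixed_points",
    "classify_stability",
    "hopf_threshold",
    "hopf_threshold_numeric",
    "first_lyapunov_coefficient",
    "classify_region",
]

#: eigenvalue real parts within this of zero are treated as zero; the
#: non-generic coincidences (parameter exactly at threshold, x2* = u/(1+u))
#: are flagged rather than forced to stable/unstable
ZERO_TOL = 1e-9

STABILITY_LABELS = ("stable", "unstable", "saddle", "center_hopf",
                    "marginal_degenerate")


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium (x, r) with its local linearisation."""

    x: float
    r: float
    kind: str                      # corner | boundary_root | interior
    eigenvalues: tuple = ()
    stability: str = ""

    def to_dict(self) -> dict:
        return {
            "x": self.x,
            "r": self.r,
            "kind": self.kind,
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "stability": self.stability,
        }

    def is_at(self, x: float, r: float, tol: float = 1e-9) -> bool:
        return abs(self.x - x) <= tol and abs(self.r - r) <= tol


@dataclass(frozen=True)
class RegionLabel:
    """Outcome class of a point in the (u, c/b) or (T, c/b) parameter plane."""

    label: str                     # bistable_interior | hopf_line |
    #                                defection_only | bistable_boundary
    stable_set: tuple = ()
    limit_cycle: bool = False

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "stable_set": [fp.to_dict() for fp in self.stable_set],
            "limit_cycle": self.limit_cycle,
        }


def find_threshold_roots(params: GameParams,
                         tol: float = 1e-14) -> tuple[float, ...]:
    """Roots of Gamma(x) b = c, the boundary equilibria x1* <= x2*.

    Gamma is unimodal with its maximum at (M-1)/(N-1), so the equation has
    zero, one (tangency) or two roots; they bracket the mode. Bisection on
    each flank to ~1e-14.
    """
    mode = params.gamma_mode
    peak = params.gamma_max
    target = params.c / params.b
    if peak < target * (1 - 1e-12):
        return ()
    if abs(peak - target) <= 1e-12 * max(peak, target):
        return (mode, mode)

    def f(x):
        return gamma(x, params) - target

    x1 = brentq(f, 0.0, mode, xtol=tol, rtol=8.9e-16)
    x2 = brentq(f, mode, 1.0, xtol=tol, rtol=8.9e-16)
    return (x1, x2)


def _interior_x(feedback: FeedbackSpec) -> float:
    if feedback.variant == "linear":
        return feedback.u / (1.0 + feedback.u)
    if feedback.variant == "exponential":
        return feedback.T
    raise ValueError("analytic equilibria require linear or exponential "
                     "feedback")


def interior_fixed_point(game: GameParams,
                         feedback: FeedbackSpec) -> Optional[tuple[float, float]]:
    """The interior equilibrium (x_int, c/(Gamma(x_int) b)), or None.

    Exists only while the equilibrium risk is strictly below 1, i.e.
    Gamma(x_int) b > c; at equality it collapses onto the r = 1 boundary
    and is reported as the boundary root instead of duplicated.
    """
    x_int = _interior_x(feedback)
    g = gamma(x_int, game)
    if g * game.b <= game.c:
        return None
    return x_int, game.c / (g * game.b)


def _eig_label(eigs: np.ndarray, tol: float = ZERO_TOL) -> str:
    re = eigs.real
    n_zero = int(np.sum(np.abs(re) <= tol))
    if n_zero == 2:
        if np.any(np.abs(eigs.imag) > tol):
            return "center_hopf"
        return "marginal_degenerate"
    if n_zero == 1:
        return "marginal_degenerate"
    if np.all(re < -tol):
        return "stable"
    if np.all(re > tol):
        return "unstable"
    return "saddle"


def classify_stability(system: CoupledSystem, point) -> str:
    """Stability label of a fixed point from the analytic Jacobian.

    Real parts within 1e-9 of zero count as zero: a purely imaginary pair
    is labelled ``center_hopf``, a single (near-)zero eigenvalue
    ``marginal_degenerate`` (e.g. the coincidence x2* = u/(1+u), which is
    left to simulation rather than resolved by a center-manifold argument).
    """
    if isinstance(point, FixedPoint):
        xy = (point.x, point.r)
    else:
        xy = (float(point[0]), float(point[1]))
    eigs = np.linalg.eigvals(jacobian(system, xy))
    return _eig_label(eigs)


def _make_fixed_point(system: CoupledSystem, x: float, r: float,
                      kind: str) -> FixedPoint:
    eigs = np.linalg.eigvals(jacobian(system, (x, r)))
    eigs = tuple(sorted((complex(ev) for ev in eigs),
                        key=lambda ev: (ev.real, ev.imag)))
    return FixedPoint(x=x, r=r, kind=kind, eigenvalues=eigs,
                      stability=_eig_label(np.array(eigs)))


def enumerate_fixed_points(system: CoupledSystem) -> list[FixedPoint]:
    """All equilibria of the coupled system, classified.

    Four corners always; boundary roots (x1*,1), (x2*,1) when Gamma(x) b = c
    has solutions (a tangency contributes a single point); the interior
    point when its risk coordinate is strictly below 1. Residual of the
    vector field at every returned point is below 1e-10.
    """
    fb = system.feedback
    if fb.variant == "custom":
        raise ValueError("analytic fixed-point enumeration supports only "
                         "linear and exponential feedback")
    pts: list[FixedPoint] = []
    for cx, cr in ((0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)):
        pts.append(_make_fixed_point(system, cx, cr, "corner"))
    roots = find_threshold_roots(system.game)
    for x in dict.fromkeys(roots):  # tangency -> single point
        pts.append(_make_fixed_point(system, x, 1.0, "boundary_root"))
    interior = interior_fixed_point(system.game, fb)
    if interior is not None:
        pts.append(_make_fixed_point(system, *interior, "interior"))
    return pts


def hopf_threshold(system_family: str, params: GameParams) -> float:
    """Closed-form Hopf threshold of the interior fixed point.

    (M-1)/(N-M) for the linear family (in u) and (M-1)/(N-1) for the
    exponential family (in T): the parameter value placing the interior x
    at the mode of the pivotality kernel, where the Jacobian trace vanishes.
    """
    N, M = params.N, params.M
    if system_family == "linear":
        return (M - 1) / (N - M)
    if system_family == "exponential":
        return (M - 1) / (N - 1)
    raise ValueError(f"unknown system family {system_family!r}")


def hopf_threshold_numeric(system_family: str, params: GameParams,
                           eps: float = 0.1, beta: float = 10.0) -> float:
    """Hopf threshold located by root-finding the interior Jacobian trace.

    Sweeps the bifurcation parameter (u or T), placing the interior fixed
    point and evaluating the trace of the analytic Jacobian there; returns
    the parameter at which the trace crosses zero. Independent check of
    :func:`hopf_threshold` (agreement to ~1e-10).
    """
    mode = params.gamma_mode

    def trace_at(x_int: float, fb: FeedbackSpec) -> float:
        sys_ = CoupledSystem(game=params, feedback=fb, eps=eps)
        r_int = params.c / (gamma(x_int, params) * params.b)
        return float(np.trace(jacobian(sys_, (x_int, r_int))))

    # bracket the interior x strictly inside the flanks of the mode
    x_lo = 0.5 * mode
    x_hi = mode + 0.5 * (1.0 - mode)

    if system_family == "linear":
        def f(u):
            fb = FeedbackSpec(variant="linear", u=u)
            return trace_at(u / (1.0 + u), fb)
        u_lo, u_hi = x_lo / (1 - x_lo), x_hi / (1 - x_hi)
        return brentq(f, u_lo, u_hi, xtol=1e-14, rtol=8.9e-16)
    if system_family == "exponential":
        def f(T):
            fb = FeedbackSpec(variant="exponential", T=T, beta=beta)
            return trace_at(T, fb)
        return brentq(f, x_lo, x_hi, xtol=1e-14, rtol=8.9e-16)
    raise ValueError(f"unknown system family {system_family!r}")


# ---------------------------------------------------------------------------
# First Lyapunov coefficient
# ---------------------------------------------------------------------------

# 4th-order-accurate central difference stencils (offset -> coefficient),
# to be divided by h**order
_STENCILS = {
    1: {-2: 1 / 12, -1: -8 / 12, 1: 8 / 12, 2: -1 / 12},
    2: {-2: -1 / 12, -1: 16 / 12, 0: -30 / 12, 1: 16 / 12, 2: -1 / 12},
    3: {-3: 1 / 8, -2: -1.0, -1: 13 / 8, 1: -13 / 8, 2: 1.0, 3: -1 / 8},
}


def _partial(fun, order_u: int, order_v: int, h: float) -> float:
    """Mixed partial d^(m+n) fun / du^m dv^n at (0, 0), 4th-order stencils."""
    total = 0.0
    su = _STENCILS[order_u] if order_u else {0: 1.0}
    sv = _STENCILS[order_v] if order_v else {0: 1.0}
    for ku, cu in su.items():
        for kv, cv in sv.items():
            total += cu * cv * fun(ku * h, kv * h)
    return total / h ** (order_u + order_v)


def first_lyapunov_coefficient(system: CoupledSystem,
                               h: float = 1e-2) -> float:
    """First Lyapunov coefficient l1 at the interior Hopf point.

    Requires the system to sit at its Hopf threshold (interior fixed point
    with |trace| <= 1e-8). The field is translated to the fixed point and
    transformed to coordinates in which the linear part is the rotation
    [[0, -w], [w, 0]]; the planar normal-form combination of second- and
    third-order partials then gives

      16 l1 = f_uuu + f_uvv + g_uuv + g_vvv
              + (1/w)[f_uv(f_uu + f_vv) - g_uv(g_uu + g_vv)
                      - f_uu g_uu + f_vv g_vv].

    Partials are 4th-order central finite differences. A negative sign means
    the bifurcation is supercritical: the emerging limit cycle is stable.
    """
    interior = interior_fixed_point(system.game, system.feedback)
    if interior is None:
        raise ValueError("no interior fixed point: the system is not at a "
                         "Hopf point")
    x0, r0 = interior
    J = jacobian(system, (x0, r0))
    tr = float(np.trace(J))
    if abs(tr) > 1e-8:
        raise ValueError(f"system is off the Hopf threshold "
                         f"(|trace| = {abs(tr):.3e} > 1e-8)")
    det = float(np.linalg.det(J))
    if det <= 0:
        raise ValueError("interior point is not of focus type (det <= 0)")
    w = np.sqrt(det)
    s = J[1, 0] / w  # r-coordinate scaling mapping J to the rotation form

    def f(u, v):
        return system_rhs(x0 + u, r0 + s * v, system)[0]

    def g(u, v):
        return system_rhs(x0 + u, r0 + s * v, system)[1] / s

    f_uuu = _partial(f, 3, 0, h)
    f_uvv = _partial(f, 1, 2, h)
    g_uuv = _partial(g, 2, 1, h)
    g_vvv = _partial(g, 0, 3, h)
    f_uv = _partial(f, 1, 1, h)
    f_uu = _partial(f, 2, 0, h)
    f_vv = _partial(f, 0, 2, h)
    g_uv = _partial(g, 1, 1, h)
    g_uu = _partial(g, 2, 0, h)
    g_vv = _partial(g, 0, 2, h)

    return (f_uuu + f_uvv + g_uuv + g_vvv
            + (f_uv * (f_uu + f_vv) - g_uv * (g_uu + g_vv)
               - f_uu * g_uu + f_vv * g_vv) / w) / 16.0


# ---------------------------------------------------------------------------
# Parameter-plane classification
# ---------------------------------------------------------------------------

def classify_region(params: GameParams, feedback: FeedbackSpec,
                    eps: float = 0.1,
                    rel_tol: float = 1e-9) -> RegionLabel:
    """Outcome class of one point of the (u, c/b) or (T, c/b) plane.

    With an interior equilibrium (Gamma(x_int) b > c): above the Hopf
    threshold the interior point is stable and coexists with the
    all-defect/high-risk corner (bistable_interior); at the threshold a
    stable limit cycle replaces it (hopf_line); below, only (0,1) attracts
    (defection_only). Without an interior point: (x2*, 1) is stable when
    x2* < x_int (bistable_boundary), otherwise defection_only.
    """
    if feedback.variant not in ("linear", "exponential"):
        raise ValueError("region classification supports only linear and "
                         "exponential feedback")
    system = CoupledSystem(game=params, feedback=feedback, eps=eps)
    x_int = _interior_x(feedback)
    param_value = feedback.u if feedback.variant == "linear" else feedback.T
    threshold = hopf_threshold(feedback.variant, params)

    fps = {("%.12g" % fp.x, "%.12g" % fp.r): fp
           for fp in enumerate_fixed_points(system)}
    corner01 = fps[("0", "1")]

    interior = interior_fixed_point(params, feedback)
    if interior is not None:
        scale = max(abs(threshold), 1.0)
        if abs(param_value - threshold) <= rel_tol * scale:
            return RegionLabel(label="hopf_line", stable_set=(corner01,),
                               limit_cycle=True)
        ip = next(fp for fp in fps.values() if fp.kind == "interior")
        if param_value > threshold:
            return RegionLabel(label="bistable_interior",
                               stable_set=(corner01, ip))
        return RegionLabel(label="defection_only", stable_set=(corner01,))

    roots = find_threshold_roots(params)
    if roots and roots[-1] < x_int:
        x2 = roots[-1]
        bp = next(fp for fp in fps.values()
                  if fp.kind == "boundary_root" and abs(fp.x - x2) < 1e-12)
        return RegionLabel(label="bistable_boundary",
                           stable_set=(corner01, bp))
    return RegionLabel(label="defection_only", stable_set=(corner01,))
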