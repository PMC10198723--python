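"""Basic phase-portrait and time-series plots.

Convenience views of the planar dynamics; aesthetics are deliberately
minimal. All functions return the matplotlib Axes so callers can decorate
or save as they wish.
"""

from __future__ import annotations

import numpy as np

from .dynamics import CoupledSystem, system_rhs
from .equilibria import enumerate_fixed_points
from .trajectories import Trajectory

__all__ = ["plot_phase_portrait", "plot_time_series"]


def plot_phase_portrait(system: CoupledSystem, trajectories=(), ax=None,
                        density: int = 20):
    """Quiver field on [0,1]^2 with fixed points and optional trajectories.

    Stable fixed points are filled circles, unstable/saddle ones open,
    degenerate ones squares.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xs = np.linspace(0.02, 0.98, density)
    rs = np.linspace(0.02, 0.98, density)
    X, R = np.meshgrid(xs, rs)
    U = np.empty_like(X)
    V = np.empty_like(R)
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            U[i, j], V[i, j] = system_rhs(X[i, j], R[i, j], system)
    speed = np.hypot(U, V)
    nz = speed > 0
    U[nz], V[nz] = U[nz] / speed[nz], V[nz] / speed[nz]
    ax.quiver(X, R, U, V, speed, cmap="viridis", width=0.004, scale=35)
    for traj in trajectories:
        ax.plot(traj.x, traj.r, lw=1.2)
        ax.plot(*traj.initial_condition, marker=".", color="k", ms=4)
    for fp in enumerate_fixed_points(system):
        if fp.stability == "stable":
            ax.plot(fp.x, fp.r, "o", mfc="k", mec="k", ms=7)
        elif fp.stability in ("center_hopf", "marginal_degenerate"):
            ax.plot(fp.x, fp.r, "s", mfc="none", mec="k", ms=7)
        else:
            ax.plot(fp.x, fp.r, "o", mfc="none", mec="k", ms=7)
    ax.set_xlim(-0.03, 1.03)
    ax.set_ylim(-0.03, 1.03)
    ax.set_xlabel("cooperator frequency $x$")
    ax.set_ylabel("risk $r$")
    return ax


def plot_time_series(traj: Trajectory, ax=None):
    """x(t) (solid) and r(t) (dashed) against time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(traj.times, traj.x, "-", color="tab:blue", label="cooperation $x$")
    ax.plot(traj.times, traj.r, "--", color="tab:red", label="risk $r$")
    ax.set_xlabel("time")
    ax.set_ylabel("level")
    ax.set_ylim(-0.03, 1.03)
    ax.legend(frameon=False)
    return ax
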