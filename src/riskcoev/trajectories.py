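"""Numerical integration, attractor detection and basins of attraction.

Small feedback speeds eps make the system stiff (fast replicator layer,
slow risk layer), so integration uses a stiff-capable adaptive scheme
(LSODA) with tight error control and dense sampling for peak detection.
States are clipped to the unit square after integration; the cumulative
clip magnitude is kept on the trajectory so boundary stickiness is visible
rather than silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .dynamics import CoupledSystem, FeedbackSpec, system_rhs
from .equilibria import FixedPoint, enumerate_fixed_points, hopf_threshold
from .game import GameParams

__all__ = ["Trajectory", "AttractorReport", "integrate", "detect_attractor",
           "basin_map", "cycle_amplitude_ladder"]

#: defaults chosen for attractor detection: limit-cycle periods at the
#: presets are O(10) time units, so 2000 units spans hundreds of cycles
DEFAULT_T_MAX = 2000.0
DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-10
SAMPLES_PER_UNIT = 10

#: detection thresholds
DRIFT_TOL = 1e-8           # |rhs| at the terminal state to call a fixed point
MATCH_TOL = 1e-4           # distance to a catalogued equilibrium
AMPLITUDE_FLOOR = 1e-3     # minimal sustained x oscillation for a cycle
PEAK_CV_MAX = 0.05         # max coefficient of variation of peak heights
MIN_PEAKS = 5


@dataclass
class Trajectory:
    """Integrated time series of (x, r)."""

    times: np.ndarray
    states: np.ndarray            # shape (n, 2), columns x and r
    system: CoupledSystem
    initial_condition: tuple[float, float]
    clip_magnitude: float = 0.0   # total amount clipped back into [0,1]^2

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def r(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def final_state(self) -> tuple[float, float]:
        return float(self.states[-1, 0]), float(self.states[-1, 1])


@dataclass
class AttractorReport:
    """Long-run behaviour detected on a trajectory."""

    kind: str                                   # fixed_point | limit_cycle |
    #                                             undetermined
    location: Optional[tuple[float, float]] = None
    period: Optional[float] = None
    x_amplitude: Optional[float] = None
    r_amplitude: Optional[float] = None
    matched_equilibrium: Optional[FixedPoint] = None
    diagnostic: str = ""

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "location": list(self.location) if self.location else None,
            "period": self.period,
            "x_amplitude": self.x_amplitude,
            "r_amplitude": self.r_amplitude,
            "matched_equilibrium": (self.matched_equilibrium.to_dict()
                                    if self.matched_equilibrium else None),
            "diagnostic": self.diagnostic,
        }


class IntegrationError(RuntimeError):
    """Solver failure; carries the last valid state."""

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


def integrate(system: CoupledSystem, x0: float, r0: float,
              t_max: float = DEFAULT_T_MAX,
              rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
              samples_per_unit: float = SAMPLES_PER_UNIT) -> Trajectory:
    """Integrate the coupled system from (x0, r0) over [0, t_max].

    Uses LSODA (adaptive, switches to BDF when the problem stiffens).
    Sampled densely enough to resolve the oscillation peaks at the study
    parameters. States are clipped to [0, 1] afterwards; the cumulative
    excursion magnitude is recorded on the trajectory.
    """
    if not (0 <= x0 <= 1 and 0 <= r0 <= 1):
        raise ValueError(f"initial condition ({x0}, {r0}) outside [0,1]^2")
    if not t_max > 0:
        raise ValueError(f"t_max must be positive (got {t_max})")
    n = max(int(round(t_max * samples_per_unit)), 200) + 1
    t_eval = np.linspace(0.0, t_max, n)
    sol = solve_ivp(system.rhs_vec, (0.0, t_max), [x0, r0], method="LSODA",
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        last = sol.y[:, -1] if sol.y.size else (x0, r0)
        raise IntegrationError(f"solver failed: {sol.message}",
                               last_state=tuple(last))
    states = sol.y.T.copy()
    clipped = np.clip(states, 0.0, 1.0)
    clip_mag = float(np.abs(states - clipped).sum())
    return Trajectory(times=sol.t, states=clipped, system=system,
                      initial_condition=(x0, r0), clip_magnitude=clip_mag)


def _drift(system: CoupledSystem, state) -> float:
    dx, dr = system_rhs(state[0], state[1], system)
    return float(np.hypot(dx, dr))


def detect_attractor(traj: Trajectory,
                     known_points: Sequence[FixedPoint] = ()) -> AttractorReport:
    """Classify the long-run behaviour of an integrated trajectory.

    Fixed point: terminal drift below 1e-8 and, when a catalogue is given,
    terminal state within 1e-4 of a catalogued equilibrium. Limit cycle:
    the x oscillation over the last quarter of the run keeps an amplitude
    above 1e-3 with at least five peaks whose heights vary by under 5%
    (period = mean inter-peak interval). Anything else: undetermined.
    """
    t, x, r = traj.times, traj.x, traj.r
    span = t[-1] - t[0]
    if span < 100.0:
        return AttractorReport(kind="undetermined",
                               diagnostic=f"trajectory spans only "
                                          f"{span:g} time units (< 100)")
    final = traj.final_state
    drift = _drift(traj.system, final)
    if drift < DRIFT_TOL:
        matched = None
        for fp in known_points:
            if np.hypot(fp.x - final[0], fp.r - final[1]) < MATCH_TOL:
                matched = fp
                break
        if matched is not None or not known_points:
            return AttractorReport(kind="fixed_point", location=final,
                                   matched_equilibrium=matched)
        return AttractorReport(kind="undetermined", location=final,
                               diagnostic="terminal drift below tolerance "
                                          "but no catalogued equilibrium "
                                          "within 1e-4")

    # last quarter of the run
    i0 = np.searchsorted(t, t[-1] - span / 4.0)
    tw, xw, rw = t[i0:], x[i0:], r[i0:]
    x_amp = float(xw.max() - xw.min()) / 2.0
    r_amp = float(rw.max() - rw.min()) / 2.0
    refractory = max(int(0.01 * len(tw)), 1)
    peaks, _ = find_peaks(xw, distance=refractory)
    if x_amp > AMPLITUDE_FLOOR and len(peaks) >= MIN_PEAKS:
        heights = xw[peaks]
        cv = float(np.std(heights) / np.mean(heights))
        if cv < PEAK_CV_MAX:
            period = float(np.mean(np.diff(tw[peaks])))
            return AttractorReport(kind="limit_cycle", period=period,
                                   x_amplitude=x_amp, r_amplitude=r_amp)
        return AttractorReport(kind="undetermined",
                               diagnostic=f"oscillation present but peak "
                                          f"heights vary by {cv:.1%} (>= 5%)")
    return AttractorReport(kind="undetermined",
                           diagnostic=f"terminal drift {drift:.2e} with x "
                                      f"amplitude {x_amp:.2e}")


def _attractor_label(report: AttractorReport) -> str:
    if report.kind == "fixed_point":
        fp = report.matched_equilibrium
        if fp is not None:
            return f"fixed_point({fp.x:.6g};{fp.r:.6g})"
        x, r = report.location
        return f"fixed_point({x:.6g};{r:.6g})"
    if report.kind == "limit_cycle":
        return "limit_cycle"
    return "undetermined"


def basin_map(system: CoupledSystem, grid_resolution: int,
              t_max: float = DEFAULT_T_MAX,
              rtol: float = 1e-8, atol: float = 1e-8,
              chunk: float = 200.0) -> list[tuple[float, float, str]]:
    """Attractor label for each point of a uniform interior grid.

    Grid points sit strictly inside (0,1)^2 at offsets k/(R+1) (the
    boundaries are invariant sets). Each point is integrated in chunks of
    ``chunk`` time units, stopping early once it parks on an equilibrium,
    up to ``t_max``. Deterministic; looser tolerances than single-trajectory
    runs since only the attractor identity is needed.
    """
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2")
    known = enumerate_fixed_points(system)
    offsets = [k / (grid_resolution + 1) for k in range(1, grid_resolution + 1)]
    out: list[tuple[float, float, str]] = []
    for r0 in offsets:
        for x0 in offsets:
            state = (x0, r0)
            elapsed, traj = 0.0, None
            while elapsed < t_max:
                step = min(chunk, t_max - elapsed)
                seg = integrate(system, state[0], state[1], t_max=step,
                                rtol=rtol, atol=atol)
                if traj is None:
                    traj = seg
                else:
                    traj = Trajectory(
                        times=np.concatenate([traj.times,
                                              seg.times[1:] + traj.times[-1]]),
                        states=np.vstack([traj.states, seg.states[1:]]),
                        system=system,
                        initial_condition=traj.initial_condition,
                        clip_magnitude=traj.clip_magnitude + seg.clip_magnitude)
                state = seg.final_state
                elapsed += step
                if _drift(system, state) < DRIFT_TOL:
                    break
            report = detect_attractor(traj, known)
            out.append((x0, r0, _attractor_label(report)))
    return out


def cycle_amplitude_ladder(family: str, params: GameParams,
                           eps: float = 0.1, beta: float = 10.0,
                           points: int = 5, span: float = 1e-3,
                           x0: float = 0.4, r0: float = 0.3,
                           t_max: float = DEFAULT_T_MAX
                           ) -> list[tuple[float, float]]:
    """Limit-cycle x amplitude as the parameter approaches the Hopf point.

    Samples ``points`` parameter values on the cycle side of the Hopf
    threshold (u or T below threshold, where the interior focus is
    unstable and the stable cycle exists), ending ``span/points`` short of
    it, integrates each from (x0, r0) and measures the x amplitude over the
    last quarter of the run. For a supercritical bifurcation the amplitude
    shrinks monotonically toward zero as the threshold is approached.

    Returns (parameter value, x amplitude) pairs ordered toward threshold.
    """
    crit = hopf_threshold(family, params)
    out: list[tuple[float, float]] = []
    for k in range(points, 0, -1):
        value = crit - span * k / points
        if family == "linear":
            fb = FeedbackSpec(variant="linear", u=value)
        else:
            fb = FeedbackSpec(variant="exponential", T=value, beta=beta)
        system = CoupledSystem(game=params, feedback=fb, eps=eps)
        traj = integrate(system, x0, r0, t_max=t_max)
        i0 = np.searchsorted(traj.times, traj.times[-1] * 0.75)
        xw = traj.x[i0:]
        out.append((value, float(xw.max() - xw.min()) / 2.0))
    return out
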