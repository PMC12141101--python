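"""Cycle-level analysis of optimized dynamic-soaring trajectories.

Given a periodic trajectory, this module computes the cycle-averaged
energy-harvest coefficient ``eta_bar = (1/T) \\int sin(2 gamma) sin(psi) dt``
and directional-flight coefficient ``epsilon_bar = (1/T) \\int cos(gamma)
sin(psi + theta) dt``, segments the cycle into energy-rise / energy-fall
phases, counts the within-cycle intervals where energy harvest dominates
directional flight (the "step-selection" structure), and sweeps the
optimizer over travel direction and shear strength to produce the
eta_bar/epsilon_bar-versus-sigma_bar trade-off table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .collocation import (
    CollocationGrid,
    InfeasibleProblemError,
    OptimalSolution,
    ProblemSpec,
    solve,
)
from .dynamics import Trajectory, epsilon, eta
from .windmodels import WindProfileConfig, mean_shear

__all__ = [
    "CycleSummary",
    "cycle_average_eta",
    "cycle_average_epsilon",
    "segment_energy_phases",
    "dominance_intervals",
    "summarize_cycle",
    "sweep_shear",
]

_PERIODICITY_WARN_TOL = 1e-3  # relative closure tolerance for U, gamma, psi, z


def _check_periodic(traj: Trajectory) -> bool:
    s = traj.states
    scale = np.array([10.0, 1.0, 1.0, 10.0])
    res = np.array([s[0, -1] - s[0, 0], s[1, -1] - s[1, 0],
                    s[2, -1] - s[2, 0], s[5, -1] - s[5, 0]])
    return bool(np.all(np.abs(res / scale) < _PERIODICITY_WARN_TOL))


def cycle_average_eta(traj: Trajectory, *, integrand: str = "sin") -> float:
    """Cycle-averaged energy-harvest coefficient (trapezoid rule).

    ``integrand="sin"`` averages ``sin(2 gamma) sin(psi)`` (the time-average
    of the instantaneous harvest coefficient).  ``integrand="cos"`` keeps the
    ``cos(psi)`` variant for sensitivity checks.
    """
    if integrand not in ("sin", "cos"):
        raise ValueError("integrand must be 'sin' or 'cos'")
    gam, psi = traj.states[1], traj.states[2]
    trig = np.sin(psi) if integrand == "sin" else np.cos(psi)
    vals = np.sin(2 * gam) * trig
    return float(np.trapezoid(vals, traj.t) / traj.T)


def cycle_average_epsilon(traj: Trajectory, theta: float) -> float:
    """Cycle-averaged directional-flight coefficient (trapezoid rule)."""
    gam, psi = traj.states[1], traj.states[2]
    return float(np.trapezoid(epsilon(gam, psi, theta), traj.t) / traj.T)


def _sign_intervals(t: np.ndarray, v: np.ndarray):
    """Maximal intervals of constant sign of ``v`` with linear zero crossing."""
    intervals = []
    sign = np.sign(v)
    start = t[0]
    cur = sign[np.argmax(sign != 0)] if np.any(sign != 0) else 0.0
    for k in range(len(t) - 1):
        a, b = v[k], v[k + 1]
        if a == 0 and b == 0:
            continue
        if a * b < 0:  # crossing inside (t_k, t_{k+1})
            tc = t[k] + (t[k + 1] - t[k]) * a / (a - b)
            intervals.append((start, tc, cur))
            start = tc
            cur = np.sign(b)
        elif cur == 0 and b != 0:
            cur = np.sign(b)
    intervals.append((start, t[-1], cur))
    return [iv for iv in intervals if iv[1] > iv[0]]


def segment_energy_phases(traj: Trajectory) -> pd.DataFrame:
    """Partition [0, T] into maximal energy-rise / energy-fall phases.

    Returns a table with columns ``t_start, t_end, duration, phase``
    (``rise`` where E_dot > 0, ``fall`` where E_dot < 0).  Phase durations
    sum to T.  An all-zero energy rate yields a single ``undefined`` phase.
    """
    e_dot = traj.energy_rate()
    if np.all(e_dot == 0):
        return pd.DataFrame([{"t_start": traj.t[0], "t_end": traj.t[-1],
                              "duration": traj.T, "phase": "undefined"}])
    rows = []
    for t0, t1, sign in _sign_intervals(traj.t, e_dot):
        rows.append({"t_start": t0, "t_end": t1, "duration": t1 - t0,
                     "phase": "rise" if sign > 0 else "fall"})
    return pd.DataFrame(rows)


def dominance_intervals(traj: Trajectory, theta: float, *,
                        min_fraction: float = 0.02):
    """Maximal intervals where energy harvest dominates (eta > epsilon).

    Intervals shorter than ``min_fraction`` of the period are merged into
    their neighbours to suppress numerical chatter at the crossings.
    Returns ``(intervals, count)`` where intervals is a list of ``(t0, t1)``.
    """
    gam, psi = traj.states[1], traj.states[2]
    diff = eta(gam, psi) - epsilon(gam, psi, theta)
    raw = _sign_intervals(traj.t, diff)
    # merge chatter: drop segments shorter than min_fraction * T by folding
    # them into the previous segment
    min_len = min_fraction * traj.T
    merged = []
    for t0, t1, sign in raw:
        if merged and (t1 - t0 < min_len or merged[-1][2] == sign):
            merged[-1] = (merged[-1][0], t1, merged[-1][2])
        else:
            merged.append((t0, t1, sign))
    # a leading runt merges forward
    if len(merged) > 1 and merged[0][1] - merged[0][0] < min_len:
        merged[1] = (merged[0][0], merged[1][1], merged[1][2])
        merged.pop(0)
    pos = [(t0, t1) for t0, t1, s in merged if s > 0]
    # periodic wrap: a dominant stretch spanning the cycle boundary is one
    # interval, not two
    n_pos = len(pos)
    if n_pos >= 2 and merged[0][2] > 0 and merged[-1][2] > 0 \
            and merged[0][0] <= traj.t[0] + 1e-12 \
            and merged[-1][1] >= traj.t[-1] - 1e-12:
        n_pos -= 1
    return pos, n_pos


@dataclass
class CycleSummary:
    """One row of the shear sweep: cycle-level metrics of an optimal cycle."""

    theta: float                 # travel direction [rad]
    W_ref: float                 # m/s
    sigma_bar: float             # 1/s
    eta_bar: float
    epsilon_bar: float
    T: float                     # s
    V_net_bar: float             # m/s
    n_eta_dominant_intervals: int
    feasible: bool = True
    phases: pd.DataFrame | None = field(default=None, repr=False)


def summarize_cycle(sol: OptimalSolution, theta: Optional[float] = None) -> CycleSummary:
    """Cycle metrics of a converged solution (theta defaults to the spec's)."""
    th = theta if theta is not None else sol.spec.theta
    if th is None:
        # free-direction solve: use the realized displacement bearing
        th = math.atan2(sol.dx, sol.dy)
    traj = sol.trajectory()
    _, n_dom = dominance_intervals(traj, th)
    return CycleSummary(
        theta=th, W_ref=sol.W_ref,
        sigma_bar=mean_shear(replace(sol.spec.wind, W_ref=sol.W_ref))
        if sol.spec.wind.family == "logarithmic" else float("nan"),
        eta_bar=cycle_average_eta(traj),
        epsilon_bar=cycle_average_epsilon(traj, th),
        T=sol.T, V_net_bar=sol.V_net_bar,
        n_eta_dominant_intervals=n_dom,
        phases=segment_energy_phases(traj),
    )


def sweep_shear(thetas: Iterable[float], W_refs: Sequence[float],
                spec_template: ProblemSpec | None = None, *,
                grid: CollocationGrid | None = None,
                seed: int = 0, n_starts: int = 3,
                maxiter: int = 300) -> pd.DataFrame:
    """Optimize max-V_net_bar cycles over (theta, W_ref) and tabulate metrics.

    Within each travel direction the W_ref axis is solved in ascending order
    with warm-started continuation (each solution seeds the next).
    Infeasible cells (below the minimum soarable wind) are marked rather than
    fatal.  Output columns: theta_deg, W_ref, sigma_bar, eta_bar,
    epsilon_bar, T, Vnet_bar, n_eta_intervals, feasible.
    """
    base = spec_template or ProblemSpec()
    grid = grid or CollocationGrid(N=40)
    rows = []
    for th in thetas:
        x0 = None
        for W in W_refs:
            spec = replace(base, objective="max_Vnet_bar", theta=th,
                           wind=replace(base.wind, W_ref=float(W)))
            try:
                try:
                    sol = solve(spec, grid,
                                n_starts=n_starts if x0 is None else 1,
                                seed=seed, x0=x0, maxiter=maxiter)
                except InfeasibleProblemError:
                    if x0 is None:
                        raise
                    # warm start failed: retry from cold seeds
                    sol = solve(spec, grid, n_starts=n_starts, seed=seed,
                                maxiter=maxiter)
            except InfeasibleProblemError:
                rows.append({"theta_deg": math.degrees(th), "W_ref": float(W),
                             "sigma_bar": mean_shear(replace(base.wind, W_ref=float(W))),
                             "eta_bar": np.nan, "epsilon_bar": np.nan,
                             "T": np.nan, "Vnet_bar": np.nan,
                             "n_eta_intervals": 0, "feasible": False})
                continue
            x0 = sol.diagnostics["x_scaled"]
            cs = summarize_cycle(sol, th)
            rows.append({"theta_deg": math.degrees(th), "W_ref": float(W),
                         "sigma_bar": cs.sigma_bar, "eta_bar": cs.eta_bar,
                         "epsilon_bar": cs.epsilon_bar, "T": cs.T,
                         "Vnet_bar": cs.V_net_bar,
                         "n_eta_intervals": cs.n_eta_dominant_intervals,
                         "feasible": True})
    return pd.DataFrame(rows)
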