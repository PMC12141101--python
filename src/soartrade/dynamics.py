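"""Point-mass 3-DOF glider dynamics in a horizontal shear wind.

State ``s = (U, gamma, psi, x, y, z)``:

* ``U`` — airspeed [m/s]
* ``gamma`` — air-relative pitch angle [rad], positive climbing
* ``psi`` — air-relative yaw angle [rad], measured from +x (East), positive
  toward +y (North)
* ``x, y, z`` — East / North / Up position [m]

Controls ``u = (C_L, phi)``: lift coefficient and roll angle [rad].
The wind blows from north to south (velocity ``(0, -W(z))``) so that a
positive shear ``sigma = dW/dz`` feeds the energy-harvest term.

Equations of motion (flat-earth, quasi-steady aerodynamics)::

    m U'     = -D - m g sin(gamma) + m sigma z' cos(gamma) sin(psi)
    m U g'   =  L cos(phi) - m g cos(gamma) - m sigma z' sin(gamma) sin(psi)
    m U p' c =  L sin(phi) + m sigma z' cos(psi)        (c = cos(gamma))
    x' = U cos(gamma) cos(psi)
    y' = U cos(gamma) sin(psi) - W(z)
    z' = U sin(gamma)

with ``L = 1/2 C_L rho S U^2`` and ``D = 1/2 C_D rho S U^2``,
``C_D = C_D0 + C_L^2 / (pi e lambda)`` (lifting-line induced drag with span
efficiency ``e``).

The mechanical energy is ``E = m g z + 1/2 m U^2`` and its rate splits into a
shear-harvest term and a drag-loss term::

    E' = E1' + E2' = 1/2 m sigma U^2 sin(2 gamma) sin(psi) - D U

which motivates the two dimensionless step-selection coefficients

* energy harvest   ``eta = sin(2 gamma) sin(psi)``
* directional flight ``epsilon = cos(gamma) sin(psi + theta)``

where ``theta`` is the travel direction measured from the wind direction
(crosswind regime: 60-120 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Tuple

import numpy as np
import pandas as pd

from .windmodels import WindProfileConfig, shear_strength, wind_speed

__all__ = [
    "GliderParams",
    "GliderState",
    "ControlInput",
    "EnergyRate",
    "Trajectory",
    "aero_forces",
    "state_derivative",
    "mechanical_energy",
    "energy_rate",
    "eta",
    "epsilon",
    "v_net",
    "integrate_trajectory",
    "IntegrationAbort",
    "SingularConfigurationError",
]


# ---------------------------------------------------------------------------
# parameters and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GliderParams:
    """Aerodynamic and structural parameters of the gliding bird.

    Defaults are the classical wandering-albatross values used in validation
    studies of dynamic-soaring trajectory optimization: mass 8.5 kg, wing
    area 0.65 m^2, wing span 3.44 m (aspect ratio b^2/S ~ 18.2), zero-lift
    drag coefficient 0.033 and span efficiency 0.92, giving the standard
    drag polar C_D = 0.033 + 0.019 C_L^2 (best glide ratio ~ 20).
    Operational limits: C_L <= 1.5, load factor n = L/(m g) <= 3, altitude
    floor z_min = 0.5 m.
    """

    m: float = 8.5            # mass [kg]
    g: float = 9.81           # gravity [m/s^2]
    S: float = 0.65           # wing area [m^2]
    rho: float = 1.225        # air density [kg/m^3]
    C_D0: float = 0.033       # zero-lift drag coefficient
    aspect_ratio: float = 3.44 ** 2 / 0.65
    e_oswald: float = 0.92    # span efficiency (k = 1/(pi e AR) ~ 0.019)
    C_L_max: float = 1.5
    n_max: float = 3.0
    z_min: float = 0.5        # altitude floor [m]

    def __post_init__(self) -> None:
        for name in ("m", "g", "S", "rho", "C_D0", "aspect_ratio",
                     "e_oswald", "C_L_max", "n_max", "z_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"GliderParams.{name} must be positive")

    @property
    def induced_drag_factor(self) -> float:
        """k in C_D = C_D0 + k C_L^2."""
        return 1.0 / (math.pi * self.e_oswald * self.aspect_ratio)

    def drag_coefficient(self, C_L):
        return self.C_D0 + self.induced_drag_factor * np.asarray(C_L) ** 2


@dataclass
class GliderState:
    U: float
    gamma: float
    psi: float
    x: float = 0.0
    y: float = 0.0
    z: float = 10.0

    def as_array(self) -> np.ndarray:
        return np.array([self.U, self.gamma, self.psi, self.x, self.y, self.z])

    def validate(self) -> None:
        if self.U <= 0:
            raise ValueError("airspeed U must be positive")
        if not (-math.pi / 2 < self.gamma < math.pi / 2):
            raise ValueError("pitch gamma must lie in (-pi/2, pi/2)")
        if self.z < 0:
            raise ValueError("altitude z must be non-negative")


@dataclass
class ControlInput:
    C_L: float
    phi: float

    def as_array(self) -> np.ndarray:
        return np.array([self.C_L, self.phi])


@dataclass
class EnergyRate:
    """Mechanical-energy rate decomposition [W]: E_dot = E1_dot + E2_dot."""
    E_dot: float
    E1_dot: float  # shear-harvest term
    E2_dot: float  # drag loss, always <= 0


class SingularConfigurationError(ValueError):
    """Raised when cos(gamma) = 0 makes the yaw equation singular."""


class IntegrationAbort(RuntimeError):
    """Trajectory left the valid state domain; carries the last valid time."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last valid t = {t_last:.3f} s)")
        self.t_last = t_last


# ---------------------------------------------------------------------------
# forces, energy, coefficients
# ---------------------------------------------------------------------------

def aero_forces(state: GliderState, ctrl: ControlInput,
                p: GliderParams) -> Tuple[float, float]:
    """Lift and drag magnitudes [N] from quasi-steady aerodynamics."""
    q = 0.5 * p.rho * p.S * state.U ** 2
    L = ctrl.C_L * q
    D = p.drag_coefficient(ctrl.C_L) * q
    return float(L), float(D)


def mechanical_energy(state: GliderState, p: GliderParams) -> float:
    """Mechanical energy E = m g z + 1/2 m U^2 [J]."""
    return p.m * p.g * state.z + 0.5 * p.m * state.U ** 2


def energy_rate(state: GliderState, ctrl: ControlInput,
                wind: WindProfileConfig, p: GliderParams) -> EnergyRate:
    """Energy-rate decomposition E_dot = harvest - drag loss.

    ``E1_dot = 1/2 m sigma U^2 sin(2 gamma) sin(psi)`` and ``E2_dot = -D U``.
    """
    sigma = shear_strength(state.z, wind, clamped=True)
    _, D = aero_forces(state, ctrl, p)
    E1 = 0.5 * p.m * sigma * state.U ** 2 * math.sin(2 * state.gamma) * math.sin(state.psi)
    E2 = -D * state.U
    return EnergyRate(E_dot=E1 + E2, E1_dot=E1, E2_dot=E2)


def eta(gamma, psi):
    """Energy harvest coefficient eta = sin(2 gamma) sin(psi), in [-1, 1]."""
    return np.sin(2.0 * np.asarray(gamma)) * np.sin(psi)


def epsilon(gamma, psi, theta):
    """Directional flight coefficient epsilon = cos(gamma) sin(psi + theta)."""
    return np.cos(np.asarray(gamma)) * np.sin(np.asarray(psi) + theta)


def v_net(state: GliderState, wind: WindProfileConfig, theta: float) -> float:
    """Net traveling speed V_net = U cos(gamma) sin(psi+theta) - W cos(theta).

    Equals the ground-velocity component along the travel direction (bearing
    ``theta`` from North in the model frame, wind blowing toward -y).
    """
    W = wind_speed(state.z, wind, clamped=True)
    return (state.U * math.cos(state.gamma) * math.sin(state.psi + theta)
            - W * math.cos(theta))


# ---------------------------------------------------------------------------
# vectorized right-hand side and analytic Jacobians
# ---------------------------------------------------------------------------

def _wind_shape(z: np.ndarray, wind: WindProfileConfig):
    """Normalized wind profile terms (w1, s1, s1p) with W = W_ref*w1 etc.

    ``w1 = W/W_ref``, ``s1 = sigma/W_ref``, ``s1p = d(s1)/dz``; heights below
    the profile's domain floor are clamped (integration context).
    """
    if wind.family == "logarithmic":
        lam = wind.log_denominator
        zc = np.maximum(z, wind.h_0)
        w1 = np.log(zc / wind.h_0) / lam
        s1 = 1.0 / (lam * zc)
        s1p = np.where(z > wind.h_0, -1.0 / (lam * zc ** 2), 0.0)
    else:
        zc = np.maximum(z, 0.0)
        e = np.exp(-zc / wind.h_ref)
        w1 = 1.0 / (1.0 + e)
        s1 = e / (wind.h_ref * (1.0 + e) ** 2)
        s1p = -e * (1.0 - e) / (wind.h_ref ** 2 * (1.0 + e) ** 3)
    return w1, s1, s1p


def rhs(s: np.ndarray, u: np.ndarray, wind: WindProfileConfig,
        p: GliderParams) -> np.ndarray:
    """Vectorized EOM right-hand side; ``s`` is (6, n), ``u`` is (2, n)."""
    U, gam, psi, _x, _y, z = s
    CL, phi = u
    w1, s1, _ = _wind_shape(np.asarray(z, dtype=float), wind)
    W = wind.W_ref * w1
    sig = wind.W_ref * s1
    kL = p.rho * p.S * CL / (2.0 * p.m)
    kD = p.rho * p.S * p.drag_coefficient(CL) / (2.0 * p.m)
    sg, cg = np.sin(gam), np.cos(gam)
    sp, cp = np.sin(psi), np.cos(psi)
    f = np.empty((6,) + np.shape(U))
    # z' = U sin(gamma) appears inside the shear coupling terms
    f[0] = -kD * U ** 2 - p.g * sg + sig * U * sg * cg * sp
    f[1] = kL * U * np.cos(phi) - p.g * cg / U - sig * sg ** 2 * sp
    f[2] = kL * U * np.sin(phi) / cg + sig * (sg / cg) * cp
    f[3] = U * cg * cp
    f[4] = U * cg * sp - W
    f[5] = U * sg
    return f


def rhs_jacobians(s: np.ndarray, u: np.ndarray, wind: WindProfileConfig,
                  p: GliderParams):
    """Analytic Jacobians of :func:`rhs`.

    Returns ``(A, B, gW)`` where ``A[i,j,k] = df_i/ds_j`` at node k (shape
    (6,6,n)), ``B[i,j,k] = df_i/du_j`` (6,2,n) and ``gW[i,k] = df_i/dW_ref``
    (6,n).  The EOMs are affine in ``W_ref`` so ``gW`` is exact.
    """
    U, gam, psi, _x, _y, z = s
    CL, phi = u
    n = np.shape(U)
    w1, s1, s1p = _wind_shape(np.asarray(z, dtype=float), wind)
    sig = wind.W_ref * s1
    sigp = wind.W_ref * s1p
    c = p.rho * p.S / (2.0 * p.m)
    kL = c * CL
    kD = c * p.drag_coefficient(CL)
    dkD_dCL = c * 2.0 * CL * p.induced_drag_factor
    sg, cg = np.sin(gam), np.cos(gam)
    sp, cp = np.sin(psi), np.cos(psi)
    sphi, cphi = np.sin(phi), np.cos(phi)
    s2g = 2.0 * sg * cg
    c2g = cg ** 2 - sg ** 2
    tg = sg / cg

    A = np.zeros((6, 6) + n)
    B = np.zeros((6, 2) + n)
    gW = np.zeros((6,) + n)

    # f0 = -kD U^2 - g sin(gam) + sig U sg cg sp
    A[0, 0] = -2 * kD * U + sig * sg * cg * sp
    A[0, 1] = -p.g * cg + sig * U * c2g * sp
    A[0, 2] = sig * U * sg * cg * cp
    A[0, 5] = sigp * U * sg * cg * sp
    B[0, 0] = -dkD_dCL * U ** 2
    gW[0] = s1 * U * sg * cg * sp

    # f1 = kL U cphi - g cg / U - sig sg^2 sp
    A[1, 0] = kL * cphi + p.g * cg / U ** 2
    A[1, 1] = p.g * sg / U - sig * s2g * sp
    A[1, 2] = -sig * sg ** 2 * cp
    A[1, 5] = -sigp * sg ** 2 * sp
    B[1, 0] = c * U * cphi
    B[1, 1] = -kL * U * sphi
    gW[1] = -s1 * sg ** 2 * sp

    # f2 = kL U sphi / cg + sig tg cp
    A[2, 0] = kL * sphi / cg
    A[2, 1] = kL * U * sphi * sg / cg ** 2 + sig * cp / cg ** 2
    A[2, 2] = -sig * tg * sp
    A[2, 5] = sigp * tg * cp
    B[2, 0] = c * U * sphi / cg
    B[2, 1] = kL * U * cphi / cg
    gW[2] = s1 * tg * cp

    # f3 = U cg cp ; f4 = U cg sp - W ; f5 = U sg
    A[3, 0] = cg * cp
    A[3, 1] = -U * sg * cp
    A[3, 2] = -U * cg * sp
    A[4, 0] = cg * sp
    A[4, 1] = -U * sg * sp
    A[4, 2] = U * cg * cp
    A[4, 5] = -sig
    gW[4] = -w1
    A[5, 0] = sg
    A[5, 1] = U * cg

    return A, B, gW


def state_derivative(state: GliderState, ctrl: ControlInput,
                     wind: WindProfileConfig, p: GliderParams) -> np.ndarray:
    """Time derivative (U', gamma', psi', x', y', z') of a single state."""
    if abs(math.cos(state.gamma)) < 1e-12:
        raise SingularConfigurationError("cos(gamma) = 0: yaw equation singular")
    state.validate()
    return rhs(state.as_array(), ctrl.as_array(), wind, p)


# ---------------------------------------------------------------------------
# trajectory container and explicit integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-indexed states and controls of a (candidate) soaring trajectory."""

    t: np.ndarray
    states: np.ndarray    # shape (6, len(t))
    controls: np.ndarray  # shape (2, len(t))
    wind: WindProfileConfig
    params: GliderParams = field(default_factory=GliderParams)

    @property
    def T(self) -> float:
        return float(self.t[-1] - self.t[0])

    def energy(self) -> np.ndarray:
        U, z = self.states[0], self.states[5]
        return self.params.m * self.params.g * z + 0.5 * self.params.m * U ** 2

    def energy_rate(self) -> np.ndarray:
        U, gam, psi, _, _, z = self.states
        CL = self.controls[0]
        sig = shear_strength(z, self.wind, clamped=True)
        D = 0.5 * self.params.rho * self.params.S * \
            self.params.drag_coefficient(CL) * U ** 2
        return (0.5 * self.params.m * sig * U ** 2 * np.sin(2 * gam) * np.sin(psi)
                - D * U)

    def to_frame(self, theta: float | None = None) -> pd.DataFrame:
        """Tidy per-node table (angles in radians, theta optional for eps/V_net)."""
        U, gam, psi, x, y, z = self.states
        df = pd.DataFrame({
            "t": self.t, "U": U, "gamma": gam, "psi": psi,
            "x": x, "y": y, "z": z,
            "CL": self.controls[0], "phi": self.controls[1],
            "E": self.energy(), "E_dot": self.energy_rate(),
            "eta": eta(gam, psi),
        })
        if theta is not None:
            W = wind_speed(z, self.wind, clamped=True)
            df["epsilon"] = epsilon(gam, psi, theta)
            df["V_net"] = U * np.cos(gam) * np.sin(psi + theta) - W * np.cos(theta)
        return df


def integrate_trajectory(s0: GliderState,
                         ctrl_schedule: Callable[[float], Tuple[float, float]],
                         wind: WindProfileConfig, p: GliderParams,
                         T: float, dt: float) -> Trajectory:
    """Explicit RK4 roll-out of the EOMs under a time-indexed control law.

    ``ctrl_schedule(t)`` returns ``(C_L, phi)``.  Raises
    :class:`IntegrationAbort` if the state leaves the valid domain
    (``z <= 0``, ``U <= 0`` or ``|gamma| -> pi/2``).
    """
    if dt <= 0 or T < dt:
        raise ValueError("require dt > 0 and T >= dt")
    n_steps = int(round(T / dt))
    t = np.linspace(0.0, n_steps * dt, n_steps + 1)
    states = np.empty((6, n_steps + 1))
    controls = np.empty((2, n_steps + 1))
    s0.validate()
    s = s0.as_array()
    states[:, 0] = s
    controls[:, 0] = ctrl_schedule(0.0)

    def f(ti, si):
        ui = np.asarray(ctrl_schedule(ti), dtype=float)
        return rhs(si, ui, wind, p)

    for k in range(n_steps):
        tk = t[k]
        k1 = f(tk, s)
        k2 = f(tk + dt / 2, s + dt / 2 * k1)
        k3 = f(tk + dt / 2, s + dt / 2 * k2)
        k4 = f(tk + dt, s + dt * k3)
        s = s + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if s[5] <= 0 or s[0] <= 0 or abs(s[1]) >= math.pi / 2 - 1e-9:
            raise IntegrationAbort("state left valid domain", t_last=tk)
        states[:, k + 1] = s
        controls[:, k + 1] = ctrl_schedule(t[k + 1])
    return Trajectory(t=t, states=states, controls=controls, wind=wind, params=p)
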