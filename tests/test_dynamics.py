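"""Glider EOMs: forces, energetics, coefficient algebra, RK4 integration."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soartrade.dynamics import (
    ControlInput,
    GliderParams,
    GliderState,
    IntegrationAbort,
    SingularConfigurationError,
    aero_forces,
    energy_rate,
    epsilon,
    eta,
    integrate_trajectory,
    mechanical_energy,
    rhs,
    state_derivative,
    v_net,
)
from soartrade.windmodels import WindProfileConfig, shear_strength

P = GliderParams()
WIND10 = WindProfileConfig(W_ref=10.0)
STILL = WindProfileConfig(W_ref=0.0)
DEG = math.pi / 180.0


class TestAeroForces:
    def test_zero_lift(self):
        s = GliderState(U=15.0, gamma=0.0, psi=0.0)
        L, D = aero_forces(s, ControlInput(C_L=0.0, phi=0.0), P)
        assert L == 0.0
        assert D == pytest.approx(0.5 * P.C_D0 * P.rho * P.S * 15 ** 2)

    def test_hand_computed_magnitudes(self):
        # pure lifting-line polar (e = 1, aspect ratio 18.2): the classic
        # hand-check L ~ 89.58 N, D ~ 4.52 N at C_L = 1, U = 15
        p = GliderParams(aspect_ratio=18.2, e_oswald=1.0)
        s = GliderState(U=15.0, gamma=0.0, psi=0.0)
        L, D = aero_forces(s, ControlInput(C_L=1.0, phi=0.0), p)
        assert L == pytest.approx(89.578125, rel=1e-9)
        assert D == pytest.approx(4.5228, abs=2e-4)

    def test_default_polar_coefficient(self):
        # default span efficiency gives the standard k ~ 0.019 polar
        assert P.induced_drag_factor == pytest.approx(0.019, abs=2e-5)


class TestEnergy:
    def test_mechanical_energy_value(self):
        s = GliderState(U=15.0, gamma=0.0, psi=0.0, z=10.0)
        assert mechanical_energy(s, P) == pytest.approx(833.85 + 956.25)

    def test_energy_scales_with_mass(self):
        s = GliderState(U=12.0, gamma=0.0, psi=0.0, z=7.0)
        p2 = replace(P, m=2 * P.m)
        assert mechanical_energy(s, p2) == pytest.approx(2 * mechanical_energy(s, P))

    def test_harvest_term_hand_value(self):
        # sigma = 1/s arranged via z and W_ref; gamma=45deg, psi=90deg, U=15
        lam = math.log(10 / 0.03)
        wind = WindProfileConfig(W_ref=2 * lam)   # sigma(z=2) = 1
        s = GliderState(U=15.0, gamma=45 * DEG, psi=90 * DEG, z=2.0)
        er = energy_rate(s, ControlInput(C_L=0.0, phi=0.0), wind, P)
        assert er.E1_dot == pytest.approx(0.5 * 8.5 * 1.0 * 225.0, rel=1e-12)

    def test_still_air_always_dissipates(self):
        s = GliderState(U=18.0, gamma=10 * DEG, psi=30 * DEG, z=5.0)
        er = energy_rate(s, ControlInput(C_L=0.8, phi=0.2), STILL, P)
        assert er.E1_dot == 0.0
        assert er.E_dot < 0
        assert er.E2_dot <= 0

    def test_zero_harvest_when_level_or_aligned(self):
        for gamma, psi in ((0.0, 1.0), (0.5, 0.0)):
            s = GliderState(U=15.0, gamma=gamma, psi=psi, z=5.0)
            er = energy_rate(s, ControlInput(C_L=0.5, phi=0.0), WIND10, P)
            assert er.E1_dot == pytest.approx(0.0, abs=1e-12)

    def test_energy_identity_against_eom(self):
        # E_dot == m g z' + m U U' assembled from the state derivative,
        # checked at 1000 random valid states
        rng = np.random.default_rng(0)
        n = 1000
        s = np.vstack([rng.uniform(5, 30, n), rng.uniform(-1.3, 1.3, n),
                       rng.uniform(-3, 3, n), np.zeros(n), np.zeros(n),
                       rng.uniform(0.1, 60, n)])
        u = np.vstack([rng.uniform(0, 1.5, n), rng.uniform(-1.4, 1.4, n)])
        f = rhs(s, u, WIND10, P)
        U, gam, psi, _, _, z = s
        lhs = P.m * P.g * f[5] + P.m * U * f[0]
        sig = shear_strength(z, WIND10, clamped=True)
        D = 0.5 * P.rho * P.S * P.drag_coefficient(u[0]) * U ** 2
        rhs_val = 0.5 * P.m * sig * U ** 2 * np.sin(2 * gam) * np.sin(psi) - D * U
        rel = np.abs(lhs - rhs_val) / np.maximum(np.abs(rhs_val), 1.0)
        assert rel.max() <= 1e-10


class TestCoefficients:
    def test_eta_extrema(self):
        assert eta(45 * DEG, 90 * DEG) == pytest.approx(1.0)
        assert eta(-45 * DEG, -90 * DEG) == pytest.approx(1.0)
        assert eta(0.0, 1.2) == pytest.approx(0.0)

    def test_epsilon_extrema(self):
        for th in (60 * DEG, 90 * DEG, 120 * DEG):
            assert epsilon(0.0, math.pi / 2 - th, th) == pytest.approx(1.0)
        assert epsilon(math.pi / 2, 0.3, 1.0) == pytest.approx(0.0, abs=1e-15)
        assert epsilon(0.0, -0.7, 0.7) == pytest.approx(0.0, abs=1e-15)

    @settings(max_examples=200, derandomize=True)
    @given(gamma=st.floats(-math.pi, math.pi),
           psi=st.floats(-math.pi, math.pi),
           theta=st.floats(0, math.pi))
    def test_bounded_in_unit_interval(self, gamma, psi, theta):
        assert -1.0 <= eta(gamma, psi) <= 1.0
        assert -1.0 <= epsilon(gamma, psi, theta) <= 1.0

    def test_v_net_examples(self):
        s = GliderState(U=15.0, gamma=0.0, psi=0.0, z=10.0)
        assert v_net(s, WIND10, math.pi / 2) == pytest.approx(15.0)
        s2 = GliderState(U=15.0, gamma=0.0, psi=30 * DEG, z=10.0)
        # W(10 m) = 10; 15 sin(90) - 10 cos(60) = 10
        assert v_net(s2, WIND10, 60 * DEG) == pytest.approx(10.0)


class TestStateDerivative:
    def test_uniform_flow_level_glide(self):
        # no shear, wings level, lift balancing weight: pure deceleration
        U = 15.0
        CL = P.m * P.g / (0.5 * P.rho * P.S * U ** 2)
        s = GliderState(U=U, gamma=0.0, psi=0.3, z=10.0)
        d = state_derivative(s, ControlInput(C_L=CL, phi=0.0), STILL, P)
        D = 0.5 * P.rho * P.S * P.drag_coefficient(CL) * U ** 2
        assert d[0] == pytest.approx(-D / P.m)
        assert d[1] == pytest.approx(0.0, abs=1e-12)
        assert d[2] == pytest.approx(0.0, abs=1e-12)

    def test_due_north_air_relative_flight(self):
        s = GliderState(U=15.0, gamma=0.0, psi=math.pi / 2, z=10.0)
        d = state_derivative(s, ControlInput(C_L=0.5, phi=0.0), WIND10, P)
        assert d[3] == pytest.approx(0.0, abs=1e-12)   # x'
        assert d[4] == pytest.approx(15.0 - 10.0)      # y' = U - W(10)
        assert d[5] == pytest.approx(0.0, abs=1e-12)   # z'

    def test_singular_pitch_raises(self):
        s = GliderState(U=15.0, gamma=math.pi / 2, psi=0.0, z=10.0)
        with pytest.raises(SingularConfigurationError):
            state_derivative(s, ControlInput(C_L=0.5, phi=0.0), WIND10, P)

    def test_invalid_state_raises(self):
        with pytest.raises(ValueError):
            state_derivative(GliderState(U=-1.0, gamma=0.0, psi=0.0, z=5.0),
                             ControlInput(0.5, 0.0), WIND10, P)


class TestIntegrateTrajectory:
    def test_still_air_energy_non_increasing(self):
        s0 = GliderState(U=18.0, gamma=0.0, psi=0.0, z=40.0)
        traj = integrate_trajectory(s0, lambda t: (0.9, 0.0), STILL, P,
                                    T=8.0, dt=0.02)
        E = traj.energy()
        assert np.all(np.diff(E) < 0)

    def test_zero_lift_ballistic_descent(self):
        s0 = GliderState(U=20.0, gamma=0.0, psi=0.0, z=60.0)
        traj = integrate_trajectory(s0, lambda t: (0.0, 0.0), STILL, P,
                                    T=2.0, dt=0.01)
        assert traj.states[5, -1] < 60.0            # falling
        assert np.all(np.diff(traj.energy()) < 0)   # drag dissipates

    def test_fourth_order_convergence(self):
        s0 = GliderState(U=16.0, gamma=5 * DEG, psi=20 * DEG, z=12.0)
        sched = lambda t: (0.9 + 0.2 * math.sin(t), 0.4 * math.cos(t))
        ref = integrate_trajectory(s0, sched, WIND10, P, T=2.0, dt=1e-4)
        errs = []
        for dt in (0.02, 0.01):
            traj = integrate_trajectory(s0, sched, WIND10, P, T=2.0, dt=dt)
            errs.append(np.abs(traj.states[:, -1] - ref.states[:, -1]).max())
        ratio = errs[0] / errs[1]
        assert 8.0 < ratio < 40.0   # ~16x for a 4th-order scheme

    def test_ground_impact_aborts(self):
        s0 = GliderState(U=20.0, gamma=-30 * DEG, psi=0.0, z=2.0)
        with pytest.raises(IntegrationAbort) as exc:
            integrate_trajectory(s0, lambda t: (0.2, 0.0), STILL, P,
                                 T=5.0, dt=0.05)
        assert exc.value.t_last >= 0.0

    def test_bad_step_arguments(self):
        s0 = GliderState(U=15.0, gamma=0.0, psi=0.0, z=10.0)
        with pytest.raises(ValueError):
            integrate_trajectory(s0, lambda t: (0.5, 0.0), STILL, P,
                                 T=1.0, dt=0.0)
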