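"""Force models, trajectory integration and outlet assignment."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import vesiflow as vf
from vesiflow.dynamics import advect_ensemble, poiseuille_exit_distance

from conftest import make_poiseuille_field, make_uniform_field


class TestForces:
    def test_elastic_force_zero_without_gradient(self, params):
        assert np.allclose(vf.elastic_force(1e-6, [0.0, 0.0], params), 0.0)

    def test_elastic_force_cubic_in_diameter(self, params):
        f1 = vf.elastic_force(1e-6, [0.0, 1.0e4], params)
        f2 = vf.elastic_force(2e-6, [0.0, 1.0e4], params)
        assert np.allclose(f2, 8.0 * f1)

    def test_elastic_force_points_to_centerline_in_poiseuille(self, params, fluid):
        fld = make_poiseuille_field(ny=81)
        vf.n1_fields(fld, fluid)
        j_low = 10   # below centerline
        j_high = 70  # above centerline
        f_low = vf.elastic_force(1e-6, fld.grad_n1[:, j_low, 5], params)
        f_high = vf.elastic_force(1e-6, fld.grad_n1[:, j_high, 5], params)
        assert f_low[1] > 0   # pushes up, toward the center
        assert f_high[1] < 0  # pushes down

    def test_elastic_toggle_disables_force(self, fluid):
        off = vf.ForceModelParams(include_elastic=False)
        assert np.allclose(vf.elastic_force(1e-6, [1e5, 1e5], off), 0.0)

    def test_drag_force_frozen_value_and_linearity(self):
        # 3*pi*1um*1.43mPa.s*1mm/s = 1.347e-11 N
        f = vf.drag_force(1e-6, 1.43e-3, [1e-3, 0.0], [0.0, 0.0])
        assert f[0] == pytest.approx(1.347e-11, rel=1e-3)
        assert np.allclose(vf.drag_force(1e-6, 1.43e-3, [2e-3, 0.0], [0.0, 0.0]), 2 * f)
        assert np.allclose(vf.drag_force(1e-6, 1.43e-3, [1.0, -2.0], [1.0, -2.0]), 0.0)

    def test_inertial_lift_disabled_by_default_and_closed_form(self):
        off = vf.ForceModelParams()
        assert vf.inertial_lift(off, 1000.0, 1.84, 3e-6, 20e-6) == 0.0
        on = vf.ForceModelParams(inertial_lift_coeff=1.0, include_inertial_lift=True)
        assert vf.inertial_lift(on, 1.0, 1.0, 1.0, 1.0) == 1.0
        assert vf.inertial_lift(on, 1000.0, 2.0, 1e-6, 2e-5) == pytest.approx(
            1.0 * 1000.0 * 4.0 * 1e-24 / 4e-10, rel=1e-12
        )

    def test_buoyancy_neutral_zero_and_antisymmetric(self):
        vol = math.pi * (3e-6) ** 3 / 6.0
        assert vf.buoyancy(1000.0, 1000.0, vol, 9.81) == 0.0
        # 50 kg/m^3 excess on a 3-um sphere: 6.94e-15 N
        f = vf.buoyancy(1050.0, 1000.0, vol, 9.81)
        assert f == pytest.approx(6.935e-15, rel=1e-3)
        assert vf.buoyancy(950.0, 1000.0, vol, 9.81) == pytest.approx(-f, rel=1e-12)

    def test_migration_velocity_scales_as_diameter_squared(self, params):
        g = [0.0, 3e4]
        v3 = vf.migration_velocity(3e-6, 1.43e-3, g, params)
        v1 = vf.migration_velocity(1e-6, 1.43e-3, g, params)
        assert np.linalg.norm(v3) / np.linalg.norm(v1) == pytest.approx(9.0, rel=1e-12)
        assert np.allclose(vf.migration_velocity(1e-6, 1.43e-3, [0.0, 0.0], params), 0.0)


class TestOverdampedLimit:
    def test_full_inertia_terminal_velocity_matches_overdamped(self, fluid, params):
        """On a frozen-gradient field the stiff system relaxes to v_mig."""
        fld = make_uniform_field(speed=0.5, length=1e-2)
        fld.gamma_dot = np.zeros_like(fld.ux)
        fld.n1 = np.zeros_like(fld.ux)
        grad = np.zeros((2,) + fld.ux.shape)
        grad[1] = 5e4  # Pa/m, constant lateral N1 gradient
        fld.grad_n1 = grad
        particle = vf.ParticleClass("1um", 1e-6)
        traj = vf.integrate_trajectory(
            fld, particle, (0.0, 15e-6), params, fluid,
            mode="full_inertia", max_steps=5000,
        )
        v_expected = vf.migration_velocity(particle.diameter, fluid.viscosity, [0.0, 5e4], params)[1]
        assert traj.vy[-1] == pytest.approx(v_expected, rel=1e-3)

    def test_overdamped_and_full_inertia_agree_on_exit_position(self, fluid, params):
        fld = make_poiseuille_field(u_mean=1.31, length=5e-5, ny=41, nx=21)
        vf.n1_fields(fld, fluid)
        particle = vf.ParticleClass("3um", 3e-6)
        start_y = 2.0e-6
        over = vf.integrate_trajectory(fld, particle, (0.0, start_y), params, fluid, mode="overdamped")
        full = vf.integrate_trajectory(
            fld, particle, (0.0, start_y), params, fluid, mode="full_inertia", max_steps=200_000
        )
        assert not over.truncated and not full.truncated
        assert abs(over.y[-1] - full.y[-1]) < 0.01 * fld.width


class TestRK4:
    def test_order_four_convergence_on_smooth_field(self):
        velocity = lambda p: np.array([0.8 + 0.3 * math.sin(3.0 * p[1]), 0.2 * math.cos(2.0 * p[0])])
        t_final = 1.0

        def endpoint(n):
            _, path = vf.rk4_path(velocity, (0.0, 0.1), t_final / n, n)
            return path[-1]

        ref = endpoint(512)
        e1 = np.linalg.norm(endpoint(16) - ref)
        e2 = np.linalg.norm(endpoint(32) - ref)
        assert 10.0 < e1 / e2 < 22.0  # ~2^4

    def test_uniform_flow_without_elasticity_keeps_streamline(self, fluid):
        fld = make_uniform_field(speed=0.5)
        vf.n1_fields(fld, fluid)  # zero everywhere
        particle = vf.ParticleClass("1um", 1e-6)
        params = vf.ForceModelParams(include_elastic=False)
        traj = vf.integrate_trajectory(fld, particle, (0.0, 7e-6), params, fluid)
        assert not traj.truncated
        assert np.abs(traj.y - 7e-6).max() < 1e-9 * fld.width

    def test_start_outside_domain_rejected(self, fluid, params):
        fld = make_uniform_field()
        with pytest.raises(ValueError):
            vf.integrate_trajectory(fld, vf.ParticleClass("1um", 1e-6), (0.0, 30e-6), params, fluid)

    def test_step_budget_exhaustion_flags_truncation(self, fluid, params):
        fld = make_poiseuille_field()
        vf.n1_fields(fld, fluid)
        traj = vf.integrate_trajectory(
            fld, vf.ParticleClass("1um", 1e-6), (0.0, 5e-6), params, fluid, max_steps=10
        )
        assert traj.truncated

    def test_wall_clearance_clamp_sets_flag(self, fluid):
        fld = make_poiseuille_field(length=5e-5)
        vf.n1_fields(fld, fluid)
        # reversed elastic sign drives the particle into the wall
        params = vf.ForceModelParams(elastic_sign=1.0)
        particle = vf.ParticleClass("3um", 3e-6)
        out = advect_ensemble(fld, particle, np.array([2.0e-6]), fluid, params)
        assert bool(out["wall_contact"][0])
        assert out["y"][0] >= particle.diameter / 2.0 - 1e-15


class TestMigrationIntegral:
    def test_exit_distance_matches_independent_ode_solution(self, fluid, params):
        """Closed-form migration integral vs direct solve_ivp of dy/dx."""
        w, u_max, length, a = 20e-6, 1.97, 3e-4, 1e-6
        pref = params.elastic_lift_coeff * a**2 / (3 * math.pi * fluid.viscosity)
        c_n1 = 2 * fluid.polymer_viscosity * fluid.relaxation_time

        def dydx(x, y):
            eta = 2 * (y[0] - w / 2) / w
            u = u_max * (1 - eta**2)
            gamma = 8 * u_max * abs(y[0] - w / 2) / w**2
            dn1_dy = c_n1 * 2 * gamma * 8 * u_max * math.copysign(1.0, y[0] - w / 2) / w**2
            return [-pref * dn1_dy / u]

        for d0 in (0.5e-6, 1.5e-6):
            sol = solve_ivp(dydx, (0.0, length), [d0], rtol=1e-10, atol=1e-13)
            got = poiseuille_exit_distance(w, u_max, fluid, params, a, d0, length)
            assert got == pytest.approx(sol.y[0, -1], rel=1e-6)

    def test_calibration_is_inverse_of_exit_distance(self, fluid, params):
        w, u_max, a = 20e-6, 1.5, 2e-6
        length = vf.calibrate_module_length(w, u_max, fluid, params, a, completion=0.05)
        exit_d = poiseuille_exit_distance(w, u_max, fluid, params, a, a / 2, length)
        assert exit_d == pytest.approx((1 - 0.05) * w / 2, rel=1e-9)


class TestOutletAssignment:
    def test_central_between_dividing_streamlines(self):
        assert vf.assign_outlet(10e-6, (6.4e-6, 13.6e-6), "O1", "side") == "O1"

    def test_wall_band_goes_to_side_outlet(self):
        assert vf.assign_outlet(1e-6, (2.5e-6, 17.5e-6), "O2", "O3") == "O3"

    def test_tie_breaks_to_wall_side(self):
        assert vf.assign_outlet(2.5e-6, (2.5e-6, 17.5e-6), "O2", "O3") == "O3"
        assert vf.assign_outlet(17.5e-6, (2.5e-6, 17.5e-6), "O2", "O3") == "O3"

    def test_truncated_trajectory_is_unassigned(self):
        traj = vf.Trajectory(
            t=np.array([0.0, 1.0]), x=np.array([0.0, 1e-5]), y=np.array([5e-6, 5e-6]),
            particle=vf.ParticleClass("1um", 1e-6), truncated=True,
        )
        assert vf.assign_outlet(traj, (2.5e-6, 17.5e-6), "O2", "O3") is None
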