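"""Flow solver, derived rheological fields and flux-split analysis."""

import math

import numpy as np
import pytest

import vesiflow as vf
from vesiflow.flowfield import FlowSolverError, solve_module_flow

from conftest import make_poiseuille_field, make_uniform_field


def cubic_flux_position(fraction: float, width: float) -> float:
    """Independent closed-form dividing streamline: solve 3s^2-2s^3 = f."""
    roots = np.roots([-2.0, 3.0, 0.0, -fraction])
    s = min(r.real for r in roots if abs(r.imag) < 1e-12 and -1e-12 <= r.real <= 1.0)
    return s * width


class TestSolver:
    def test_straight_channel_matches_poiseuille(self, module1_field, geometry, conditions):
        u_mean = conditions.total / (geometry.height * geometry.width_module1)
        s = module1_field.y / module1_field.width
        analytic = 6.0 * u_mean * s * (1.0 - s)
        mid = module1_field.ux[:, module1_field.x.size // 2]
        assert np.abs(mid - analytic).max() / analytic.max() < 0.01

    def test_mass_conserved_through_every_cross_section(self, module1_field):
        flux = np.trapezoid(module1_field.ux, module1_field.y, axis=0)
        assert np.abs(flux / flux[0] - 1.0).max() < 0.005

    def test_no_slip_walls(self, module1_field):
        assert np.abs(module1_field.ux[0, :]).max() == 0.0
        assert np.abs(module1_field.ux[-1, :]).max() == 0.0

    def test_discrete_divergence_free(self, module1_field):
        div = (
            np.gradient(module1_field.ux, module1_field.dx, axis=1)
            + np.gradient(module1_field.uy, module1_field.dy, axis=0)
        )
        scale = module1_field.u_max / module1_field.width
        assert np.abs(div[1:-1, 1:-1]).max() < 1e-6 * scale

    def test_developing_plug_flow_is_symmetric(self, fluid):
        fld = solve_module_flow(
            20e-6, 1e-4, 55e-6, 1e-9, fluid, ny=21, nx=51, inflow="plug", tol=1e-6
        )
        assert np.abs(fld.ux - fld.ux[::-1, :]).max() < 1e-3 * fld.u_max

    def test_grid_refinement_reduces_flux_imbalance(self, fluid):
        def imbalance(ny):
            fld = solve_module_flow(
                20e-6, 1e-4, 55e-6, 1e-9, fluid, ny=ny, nx=41, inflow="plug", tol=1e-6
            )
            flux = np.trapezoid(fld.ux, fld.y, axis=0)
            return np.abs(flux / flux[0] - 1.0).max()

        assert imbalance(21) < imbalance(11)

    def test_stokes_and_navier_stokes_developed_profiles_agree(self, fluid):
        kw = dict(ny=21, nx=41, tol=1e-8)
        ns = solve_module_flow(20e-6, 2e-4, 55e-6, 1.444e-9, fluid, **kw)
        stk = solve_module_flow(20e-6, 2e-4, 55e-6, 1.444e-9, fluid, stokes=True, **kw)
        dev = np.abs(ns.ux[:, -2] - stk.ux[:, -2]).max() / ns.u_max
        assert dev < 0.02

    def test_nonconvergence_raises_with_residual_history(self, fluid):
        with pytest.raises(FlowSolverError) as err:
            solve_module_flow(20e-6, 1e-4, 55e-6, 1e-9, fluid, ny=21, nx=41,
                              inflow="plug", tol=1e-12, max_iter=3)
        assert len(err.value.residuals) == 3

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            vf.DeviceGeometry(width_module1=-1.0)
        with pytest.raises(ValueError):
            vf.DeviceGeometry(central_fraction_module1=1.5)

    def test_conditions_validation(self):
        with pytest.raises(ValueError):
            vf.FlowConditions(q_sample=-1e-9)
        with pytest.raises(ValueError):
            vf.FlowConditions(q_sample=0.0, q_guide1=0.0, q_guide2=0.0)


class TestDerivedFields:
    def test_uniform_translation_has_zero_shear(self):
        fld = make_uniform_field()
        scale = fld.u_max / fld.width
        assert np.abs(vf.shear_rate_field(fld)).max() < 1e-12 * scale

    def test_linear_shear_gives_rate_magnitude(self):
        fld = make_uniform_field()
        k = 123.0
        fld.ux = k * np.repeat(fld.y[:, None], fld.x.size, axis=1)
        gamma = vf.shear_rate_field(fld)
        assert np.allclose(gamma, k, rtol=1e-9)

    def test_poiseuille_wall_shear_rate(self):
        u_mean = 1.3
        fld = make_poiseuille_field(u_mean=u_mean)
        gamma = vf.shear_rate_field(fld)
        assert gamma[0, 5] == pytest.approx(6.0 * u_mean / fld.width, rel=1e-9)
        assert gamma[fld.y.size // 2, 5] == pytest.approx(0.0, abs=1e-9 * gamma.max())

    def test_n1_profile_shape_and_scaling(self, fluid):
        fld = make_poiseuille_field(ny=81)
        n1, grad = vf.n1_fields(fld, fluid)
        mid = fld.y.size // 2
        assert n1[0, 5] == n1.max()
        assert n1[mid, 5] == pytest.approx(0.0, abs=1e-12 * n1.max())
        # lateral gradient vanishes at the centerline by symmetry
        assert grad[1][mid, 5] == pytest.approx(0.0, abs=1e-9 * np.abs(grad[1]).max())
        # velocity scale k -> N1 scale k^2
        fld2 = make_poiseuille_field(u_mean=2.0, ny=81)
        n1b, _ = vf.n1_fields(fld2, fluid)
        assert np.allclose(n1b, 4.0 * n1, rtol=1e-9)

    def test_zero_shear_means_zero_n1_everywhere(self, fluid):
        fld = make_uniform_field()
        n1, grad = vf.n1_fields(fld, fluid)
        scale = vf.first_normal_stress(fld.u_max / fld.width, fluid.polymer_viscosity, fluid.relaxation_time)
        assert np.abs(n1).max() < 1e-12 * scale
        assert np.abs(grad).max() < 1e-12 * scale / fld.width


class TestFluxSplit:
    def test_bisection_matches_closed_form_cubic_within_nanometer(self):
        fld = make_poiseuille_field(ny=41)
        for frac in (0.0859375 / 2.0, 0.2416640, 0.3, 0.05):
            found = vf.dividing_streamline(fld, frac, wall="lower")
            assert abs(found - cubic_flux_position(frac, fld.width)) < 1e-9

    def test_default_splits_place_streamlines_at_design_marks(self, module1_field, module2_field, geometry):
        side1 = (1.0 - geometry.central_fraction_module1) / 2.0
        d1 = vf.dividing_streamline(module1_field, side1, wall="lower")
        assert d1 == pytest.approx(6.4e-6, abs=5e-9)
        d2 = vf.dividing_streamline(module2_field, geometry.side_fraction_module2 / 2.0, wall="lower")
        assert d2 == pytest.approx(2.5e-6, abs=5e-9)

    def test_symmetric_pair_mirrors(self, module1_field):
        lo, hi = vf.dividing_streamline(module1_field, 0.2, wall="both")
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_fraction_limit_approaches_far_wall(self):
        fld = make_poiseuille_field()
        assert vf.dividing_streamline(fld, 1.0 - 1e-9, wall="lower") == pytest.approx(fld.width, abs=1e-8)

    def test_fraction_out_of_range_rejected(self):
        fld = make_poiseuille_field()
        for frac in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                vf.dividing_streamline(fld, frac)

    def test_cumulative_flux_strictly_increasing(self, module1_field):
        f = vf.cumulative_flux(module1_field)
        ys = np.linspace(0, module1_field.width, 301)
        assert np.all(np.diff(f(ys)) > 0)

    def test_sample_band_carries_inlet_share(self, module1_field, conditions):
        lo, hi = vf.sample_stream_width(module1_field, conditions)
        f = vf.cumulative_flux(module1_field)
        total = float(f(module1_field.width))
        share = conditions.sample_fraction  # 200/5200 of total flux
        assert share == pytest.approx(200.0 / 5200.0, rel=1e-12)
        got = (float(f(lo)) + total - float(f(module1_field.width - hi))) / total
        assert got == pytest.approx(share, rel=1e-6)

    def test_plug_profile_band_width_is_flux_fraction_times_width(self, conditions):
        fld = make_uniform_field()
        lo, hi = vf.sample_stream_width(fld, conditions)
        expect = conditions.sample_fraction / 2.0 * fld.width
        assert lo == pytest.approx(expect, rel=1e-9)
        assert hi == pytest.approx(expect, rel=1e-9)

    def test_sample_taking_all_flow_spans_the_channel(self):
        fld = make_poiseuille_field()
        cond = vf.FlowConditions(q_sample=1e-9, q_guide1=0.0, q_guide2=0.0)
        lo, hi = vf.sample_stream_width(fld, cond)
        assert lo + hi == pytest.approx(fld.width)
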