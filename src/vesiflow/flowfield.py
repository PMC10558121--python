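"""Steady 2D channel flow and dividing-streamline (flux-split) analysis.

The separation device is modelled, as in the underlying physics, as a planar
(2D) incompressible Newtonian flow: at the dilute polymer concentrations used,
the shear viscosity is rate-independent, so elasticity enters only through the
particle force model (:mod:`vesiflow.dynamics`), not the velocity field.
Volumetric rates are converted to depth-averaged 2D velocities through the
uniform channel height ``H`` (Q -> Q/(w*H)).

Each module of the two-module device (cell depletion, then sEV isolation) is a
straight rectangular channel solved on a structured grid with a
streamfunction-vorticity formulation:

    lap(psi) = -omega,      u = dpsi/dy,  v = -dpsi/dx,
    u.grad(omega) = nu * lap(omega)      (convective term toggleable)

with a prescribed inflow profile, no-slip walls (Thom wall vorticity) and
zero-gradient outflow.  The streamfunction is also the cumulative lateral
flux, which makes the dividing-streamline analysis exact: the streamline
separating fluid destined for different outlets sits where the cumulative
flux from the wall equals that outlet's flux fraction.

Outlet junction geometry is deliberately not resolved; outlets are
represented by their flux fractions and located by the dividing-streamline
root find (1 nm tolerance), which is all the downstream trajectory analysis
requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline, RegularGridInterpolator
from scipy.optimize import brentq

from .rheology import FluidSpec, first_normal_stress

__all__ = [
    "DeviceGeometry",
    "FlowConditions",
    "FlowField",
    "FlowSolverError",
    "poiseuille_flux_fraction",
    "solve_module_flow",
    "solve_flow",
    "shear_rate_field",
    "n1_fields",
    "cumulative_flux",
    "dividing_streamline",
    "sample_stream_width",
]


def poiseuille_flux_fraction(distance: float, width: float) -> float:
    """Fraction of total flux carried between one wall and a streamline.

    For the plane-Poiseuille parabola the normalized cumulative flux from a
    wall is the cubic ``3 s^2 - 2 s^3`` with ``s = distance/width``.  Used to
    express default outlet flux fractions in terms of the dividing-streamline
    marks they correspond to.
    """
    s = distance / width
    if not 0.0 <= s <= 1.0:
        raise ValueError("distance must lie within the channel width")
    return 3.0 * s**2 - 2.0 * s**3


# Default outlet flux fractions: chosen so the dividing streamlines of a
# fully developed profile sit 6.4 um (module 1, central outlet) and 2.5 um
# (module 2, side outlets combined) from the sidewalls of a 20-um channel.
_W_DEFAULT = 20e-6
_CENTRAL_FRACTION_M1 = 1.0 - 2.0 * poiseuille_flux_fraction(6.4e-6, _W_DEFAULT)
_SIDE_FRACTION_M2 = 2.0 * poiseuille_flux_fraction(2.5e-6, _W_DEFAULT)


@dataclass(frozen=True)
class DeviceGeometry:
    """Parametric two-module device geometry.

    Lengths default to values produced by the migration-completion
    calibration in :func:`vesiflow.dynamics.calibrate_module_length` (the
    smallest length for which the largest particle class in each module
    finishes its lateral migration at the default operating point).  Outlet
    flux fractions default to the values that place the dividing streamlines
    at 6.4 um from the sidewalls in module 1 and 2.5 um in module 2.
    """

    width_module1: float = _W_DEFAULT
    length_module1: float = 2.8e-4
    width_module2: float = _W_DEFAULT
    length_module2: float = 3.6e-3
    height: float = 55e-6
    central_fraction_module1: float = _CENTRAL_FRACTION_M1
    side_fraction_module2: float = _SIDE_FRACTION_M2

    def __post_init__(self) -> None:
        for name in ("width_module1", "length_module1", "width_module2", "length_module2", "height"):
            if not getattr(self, name) > 0:
                raise ValueError(f"DeviceGeometry.{name} must be positive")
        for name in ("central_fraction_module1", "side_fraction_module2"):
            frac = getattr(self, name)
            if not 0.0 < frac < 1.0:
                raise ValueError(f"DeviceGeometry.{name} must lie in (0, 1)")


@dataclass(frozen=True)
class FlowConditions:
    """Volumetric inlet flow rates (m^3/s) and PEO concentrations (metadata).

    ``q_sample`` is the (blood) sample inlet pinched along both sidewalls;
    ``q_guide1`` and ``q_guide2`` are the particle-free guide streams.
    Defaults are the working point 200 / 2000 / 3000 ul/hour.
    """

    q_sample: float = 200e-9 / 3600.0
    q_guide1: float = 2000e-9 / 3600.0
    q_guide2: float = 3000e-9 / 3600.0
    peo_concentrations: tuple[float, float, float] = (0.001, 0.0015, 0.001)

    def __post_init__(self) -> None:
        rates = (self.q_sample, self.q_guide1, self.q_guide2)
        if any(q < 0 for q in rates):
            raise ValueError("flow rates must be non-negative")
        if not any(q > 0 for q in rates):
            raise ValueError("at least one inlet flow rate must be positive")

    @property
    def total(self) -> float:
        return self.q_sample + self.q_guide1 + self.q_guide2

    @property
    def sample_fraction(self) -> float:
        return self.q_sample / self.total


class FlowSolverError(RuntimeError):
    """Raised when the flow solver does not converge; carries residual history."""

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class FlowField:
    """Solved flow on a structured grid (arrays indexed ``[y, x]``).

    ``psi`` is the streamfunction; ``psi(y) - psi(wall)`` is the cumulative
    lateral flux per unit depth, the quantity all flux-split analysis uses.
    Derived rheological fields (``gamma_dot``, ``n1``, ``grad_n1``) are filled
    by :func:`shear_rate_field` / :func:`n1_fields`.
    """

    x: np.ndarray
    y: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    psi: np.ndarray
    p: np.ndarray
    width: float
    length: float
    height: float
    flow_rate: float
    residuals: list[float] = field(default_factory=list)
    gamma_dot: np.ndarray | None = None
    n1: np.ndarray | None = None
    grad_n1: np.ndarray | None = None

    @property
    def u_max(self) -> float:
        return float(np.abs(self.ux).max())

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    def velocity_interpolators(self):
        """(ux, uy) interpolators over (y, x), clamped at the boundaries."""
        kw = dict(bounds_error=False, fill_value=None, method="linear")
        ix = RegularGridInterpolator((self.y, self.x), self.ux, **kw)
        iy = RegularGridInterpolator((self.y, self.x), self.uy, **kw)
        return ix, iy

    def column_index(self, x_station: float | None) -> int:
        if x_station is None:
            return self.x.size - 1
        if not self.x[0] <= x_station <= self.x[-1]:
            raise ValueError("axial station outside the solved domain")
        return int(np.argmin(np.abs(self.x - x_station)))


def _inflow_profile(kind: str, y: np.ndarray, width: float, q2d: float):
    """Inflow velocity, streamfunction and vorticity profiles."""
    s = y / width
    u_mean = q2d / width
    if kind == "parabolic":
        u = 6.0 * u_mean * s * (1.0 - s)
        psi = q2d * (3.0 * s**2 - 2.0 * s**3)
        omega = -6.0 * u_mean * (1.0 - 2.0 * s) / width
    elif kind == "plug":
        u = np.full_like(y, u_mean)
        u[0] = u[-1] = 0.0
        psi = q2d * s
        omega = np.zeros_like(y)
        dy = y[1] - y[0]
        omega[0] = -u_mean / dy
        omega[-1] = u_mean / dy
    else:
        raise ValueError(f"unknown inflow profile {kind!r}")
    return u, psi, omega


def solve_module_flow(
    width: float,
    length: float,
    height: float,
    flow_rate: float,
    fluid: FluidSpec,
    ny: int = 41,
    nx: int = 201,
    inflow: Literal["parabolic", "plug"] = "parabolic",
    stokes: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> FlowField:
    """Solve steady incompressible flow in one straight module channel.

    Streamfunction-vorticity iteration: SOR sweeps on the psi Poisson
    equation interleaved with red-black Gauss-Seidel sweeps on the steady
    vorticity transport equation (first-order upwind convection, disabled in
    ``stokes`` mode).  Converged when the joint dimensionless residual falls
    below ``tol``; raises :class:`FlowSolverError` with the residual history
    otherwise.
    """
    if ny < 5 or nx < 5:
        raise ValueError("grid must have at least 5 points per direction")
    if flow_rate <= 0:
        raise ValueError("flow rate must be positive")
    q2d = flow_rate / height  # per-unit-depth flux, m^2/s
    nu = fluid.viscosity / fluid.density
    y = np.linspace(0.0, width, ny)
    x = np.linspace(0.0, length, nx)
    dy = y[1] - y[0]
    dx = x[1] - x[0]

    u_in, psi_in, omega_in = _inflow_profile(inflow, y, width, q2d)
    psi = np.repeat(psi_in[:, None], nx, axis=1)
    omega = np.repeat(omega_in[:, None], nx, axis=1)

    # red-black masks for interior points
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    red = ((jj + ii) % 2 == 0)[1:-1, 1:-1]
    inv_dx2, inv_dy2 = 1.0 / dx**2, 1.0 / dy**2
    diag = 2.0 * (inv_dx2 + inv_dy2)
    sor = 2.0 / (1.0 + math.sin(math.pi / min(nx, ny)))

    omega_scale = max(float(np.abs(omega_in).max()), 6.0 * q2d / width**2)
    residuals: list[float] = []

    def apply_psi_bc() -> None:
        psi[:, 0] = psi_in
        psi[0, :] = 0.0
        psi[-1, :] = q2d
        psi[:, -1] = psi[:, -2]

    def velocities():
        ux = np.gradient(psi, dy, axis=0)
        uy = -np.gradient(psi, dx, axis=1)
        ux[0, :] = 0.0
        ux[-1, :] = 0.0
        uy[0, :] = 0.0
        uy[-1, :] = 0.0
        return ux, uy

    for it in range(max_iter):
        # --- psi Poisson sweeps (SOR, red-black) ---
        for _ in range(3):
            apply_psi_bc()
            for mask in (red, ~red):
                interior = (
                    (psi[1:-1, 2:] + psi[1:-1, :-2]) * inv_dx2
                    + (psi[2:, 1:-1] + psi[:-2, 1:-1]) * inv_dy2
                    + omega[1:-1, 1:-1]
                ) / diag
                block = psi[1:-1, 1:-1]
                block[mask] += sor * (interior[mask] - block[mask])
                apply_psi_bc()

        ux, uy = velocities()

        # --- vorticity boundary conditions ---
        omega[:, 0] = omega_in
        omega[0, :] = 2.0 * (psi[0, :] - psi[1, :]) * inv_dy2  # Thom, lower wall
        omega[-1, :] = 2.0 * (psi[-1, :] - psi[-2, :]) * inv_dy2  # Thom, upper wall
        omega[:, -1] = omega[:, -2]

        # --- steady vorticity transport, upwind GS (red-black) ---
        if stokes:
            ax_p = ax_m = ay_p = ay_m = 0.0
        else:
            uxc = ux[1:-1, 1:-1]
            uyc = uy[1:-1, 1:-1]
            ax_p = np.maximum(uxc, 0.0) / dx
            ax_m = np.maximum(-uxc, 0.0) / dx
            ay_p = np.maximum(uyc, 0.0) / dy
            ay_m = np.maximum(-uyc, 0.0) / dy
        denom = nu * diag + ax_p + ax_m + ay_p + ay_m
        for mask in (red, ~red):
            rhs = (
                nu * (omega[1:-1, 2:] + omega[1:-1, :-2]) * inv_dx2
                + nu * (omega[2:, 1:-1] + omega[:-2, 1:-1]) * inv_dy2
                + ax_p * omega[1:-1, :-2]
                + ax_m * omega[1:-1, 2:]
                + ay_p * omega[:-2, 1:-1]
                + ay_m * omega[2:, 1:-1]
            )
            block = omega[1:-1, 1:-1]
            block[mask] = (rhs / denom)[mask]

        # --- residuals (dimensionless) ---
        lap_psi = (
            (psi[1:-1, 2:] - 2 * psi[1:-1, 1:-1] + psi[1:-1, :-2]) * inv_dx2
            + (psi[2:, 1:-1] - 2 * psi[1:-1, 1:-1] + psi[:-2, 1:-1]) * inv_dy2
        )
        res_psi = float(np.abs(lap_psi + omega[1:-1, 1:-1]).max()) / omega_scale
        lap_om = (
            (omega[1:-1, 2:] - 2 * omega[1:-1, 1:-1] + omega[1:-1, :-2]) * inv_dx2
            + (omega[2:, 1:-1] - 2 * omega[1:-1, 1:-1] + omega[:-2, 1:-1]) * inv_dy2
        )
        if stokes:
            conv = 0.0
        else:
            domx = np.where(
                ux[1:-1, 1:-1] >= 0,
                (omega[1:-1, 1:-1] - omega[1:-1, :-2]) / dx,
                (omega[1:-1, 2:] - omega[1:-1, 1:-1]) / dx,
            )
            domy = np.where(
                uy[1:-1, 1:-1] >= 0,
                (omega[1:-1, 1:-1] - omega[:-2, 1:-1]) / dy,
                (omega[2:, 1:-1] - omega[1:-1, 1:-1]) / dy,
            )
            conv = ux[1:-1, 1:-1] * domx + uy[1:-1, 1:-1] * domy
        res_om = float(np.abs(conv - nu * lap_om).max()) / (nu * omega_scale * diag)
        res = max(res_psi, res_om)
        residuals.append(res)
        if res < tol:
            break
    else:
        raise FlowSolverError(
            f"flow solver did not reach tolerance {tol:g} within {max_iter} iterations "
            f"(final residual {residuals[-1]:.3e})",
            residuals,
        )

    ux, uy = velocities()
    p = _pressure_from_momentum(x, y, ux, uy, fluid, stokes)
    return FlowField(
        x=x, y=y, ux=ux, uy=uy, psi=psi, p=p,
        width=width, length=length, height=height, flow_rate=flow_rate,
        residuals=residuals,
    )


def _pressure_from_momentum(x, y, ux, uy, fluid: FluidSpec, stokes: bool) -> np.ndarray:
    """Post-processed pressure: integrate the x-momentum balance upstream.

    Diagnostic only (trajectories never use p); exact for fully developed
    flow, approximate elsewhere.
    """
    dx = x[1] - x[0]
    dy = y[1] - y[0]
    eta = fluid.viscosity
    lap_ux = np.zeros_like(ux)
    lap_ux[1:-1, 1:-1] = (
        (ux[1:-1, 2:] - 2 * ux[1:-1, 1:-1] + ux[1:-1, :-2]) / dx**2
        + (ux[2:, 1:-1] - 2 * ux[1:-1, 1:-1] + ux[:-2, 1:-1]) / dy**2
    )
    lap_ux[0, :] = lap_ux[1, :]
    lap_ux[-1, :] = lap_ux[-2, :]
    dpdx = eta * lap_ux
    if not stokes:
        dux_dx = np.gradient(ux, dx, axis=1)
        dux_dy = np.gradient(ux, dy, axis=0)
        dpdx = dpdx - fluid.density * (ux * dux_dx + uy * dux_dy)
    p = np.zeros_like(ux)
    for i in range(x.size - 2, -1, -1):
        p[:, i] = p[:, i + 1] - 0.5 * (dpdx[:, i] + dpdx[:, i + 1]) * dx
    return p


def solve_flow(
    geometry: DeviceGeometry,
    conditions: FlowConditions,
    fluid: FluidSpec,
    module: Literal[1, 2] = 1,
    **solver_kwargs,
) -> FlowField:
    """Solve the flow in one module of the device.

    Module 1 carries the combined sample + guide flux; module 2 carries only
    the module-1 side-outlet streams, i.e. the non-central flux fraction.
    """
    if module == 1:
        width, length = geometry.width_module1, geometry.length_module1
        rate = conditions.total
    elif module == 2:
        width, length = geometry.width_module2, geometry.length_module2
        rate = conditions.total * (1.0 - geometry.central_fraction_module1)
    else:
        raise ValueError("module must be 1 or 2")
    return solve_module_flow(width, length, geometry.height, rate, fluid, **solver_kwargs)


def shear_rate_field(fld: FlowField) -> np.ndarray:
    """Shear-rate magnitude gamma_dot = sqrt(2 D:D), D the strain-rate tensor.

    For 2D flow this is sqrt(2 ux_x^2 + 2 uy_y^2 + (ux_y + uy_x)^2); stored on
    the field and returned.
    """
    if fld.ux is None or fld.uy is None:
        raise RuntimeError("flow field has no velocity data")
    dux_dx = np.gradient(fld.ux, fld.dx, axis=1, edge_order=2)
    dux_dy = np.gradient(fld.ux, fld.dy, axis=0, edge_order=2)
    duy_dx = np.gradient(fld.uy, fld.dx, axis=1, edge_order=2)
    duy_dy = np.gradient(fld.uy, fld.dy, axis=0, edge_order=2)
    gamma = np.sqrt(2.0 * dux_dx**2 + 2.0 * duy_dy**2 + (dux_dy + duy_dx) ** 2)
    fld.gamma_dot = gamma
    return gamma


def n1_fields(fld: FlowField, fluid: FluidSpec) -> tuple[np.ndarray, np.ndarray]:
    """First normal stress difference N1 and its gradient on the grid.

    N1 is the Oldroyd-B pointwise map of the shear rate; the gradient uses
    central differences (one-sided at boundaries).  Returns ``(n1, grad_n1)``
    with ``grad_n1`` shaped ``(2, ny, nx)`` as (d/dx, d/dy).
    """
    if fld.gamma_dot is None:
        shear_rate_field(fld)
    n1 = first_normal_stress(fld.gamma_dot, fluid.polymer_viscosity, fluid.relaxation_time)
    dn1_dy, dn1_dx = np.gradient(n1, fld.dy, fld.dx, edge_order=2)
    fld.n1 = n1
    fld.grad_n1 = np.stack([dn1_dx, dn1_dy])
    return n1, fld.grad_n1


def cumulative_flux(fld: FlowField, x_station: float | None = None) -> CubicSpline:
    """Cumulative lateral flux F(y) (m^2/s per depth) at an axial station.

    Taken directly from the streamfunction, F(y) = psi(y) - psi(0), and
    interpolated with a not-a-knot cubic spline so that the fully developed
    cubic profile is reproduced exactly.  F is strictly increasing from wall
    to wall, guaranteeing unique dividing-streamline roots.
    """
    col = fld.column_index(x_station)
    return CubicSpline(fld.y, fld.psi[:, col] - fld.psi[0, col])


def dividing_streamline(
    fld: FlowField,
    flux_fraction: float,
    wall: Literal["lower", "upper", "both"] = "both",
    x_station: float | None = None,
) -> float | tuple[float, float]:
    """Lateral position of the streamline bounding an outlet's flux share.

    Returns the distance from the given sidewall at which the cumulative flux
    between wall and streamline equals ``flux_fraction`` of the total flux
    through the section.  Root located by bracketed bisection (brentq) on the
    cumulative-flux spline to well below 1 nm.  With ``wall="both"`` returns
    the (lower, upper) pair, e.g. for a central outlet flanked by two side
    streams each carrying ``(1 - central)/2``.
    """
    if not 0.0 < flux_fraction < 1.0:
        raise ValueError("flux fraction must lie strictly inside (0, 1)")
    fcum = cumulative_flux(fld, x_station)
    total = float(fcum(fld.width))

    def from_lower(frac: float) -> float:
        target = frac * total
        return brentq(lambda yy: fcum(yy) - target, 0.0, fld.width, xtol=1e-12)

    if wall == "lower":
        return from_lower(flux_fraction)
    if wall == "upper":
        return fld.width - from_lower(1.0 - flux_fraction)
    return from_lower(flux_fraction), fld.width - from_lower(1.0 - flux_fraction)


def sample_stream_width(fld: FlowField, conditions: FlowConditions, x_station: float | None = None) -> tuple[float, float]:
    """Width of the wall-adjacent sample bands at a station.

    The sample inlet flux (share ``q_sample / total``) is pinched into two
    equal bands, one along each sidewall; returns their widths (lower, upper),
    found by the same cumulative-flux root find as the dividing streamlines.
    """
    share = conditions.sample_fraction / 2.0
    if share == 0:
        return 0.0, 0.0
    if share >= 0.5:
        return fld.width / 2.0, fld.width / 2.0
    lower = dividing_streamline(fld, share, wall="lower", x_station=x_station)
    upper = dividing_streamline(fld, share, wall="upper", x_station=x_station)
    return lower, upper
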