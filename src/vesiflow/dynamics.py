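"""Particle force balance, Lagrangian tracking and outlet routing.

A rigid particle of diameter ``a`` suspended in the flowing viscoelastic
medium experiences, in order of importance here:

* an elastic lift ``F_e = C_e * a**3 * grad(N1)`` directed toward decreasing
  first normal stress difference (toward the low-shear channel centerline),
* Stokes drag ``F_d = 3*pi*a*eta*(u - v_p)``,
* an inertial lift ``F_i = C_i * rho_f * u_max**2 * a**4 / w**2`` (negligible
  at the particle Reynolds numbers of this device; off by default),
* a virtual-mass force ``0.5 * rho_f * V_p * (Du/Dt - dv_p/dt)`` from the
  relative acceleration of particle and displaced fluid,
* buoyancy ``(rho_p - rho_f) * V_p * g`` (zero for neutrally buoyant
  particles; off by default).

Newton's second law for the particle velocity has relaxation times of
1e-10 to 1e-7 s against millisecond channel transits, so the default
integration is the overdamped limit, where drag balances the elastic lift and
the particle moves with ``u + v_mig``, ``v_mig = C_e*a**2*grad(N1)/(3*pi*eta)``
toward the centerline.  The stiff full-inertia system is retained (with the
``-dv_p/dt`` half of the virtual-mass force folded into an effective mass
``(rho_p + rho_f/2)*V_p``) for validation at small time steps.  Both modes
advance with classical fixed-step RK4 on bilinearly interpolated fields.

Because the elastic lift scales as ``a**3`` against drag's ``a``, migration
speed scales as ``a**2``: large particles reach the centerline quickly while
small ones linger near the walls, which is the entire separation principle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .flowfield import (
    DeviceGeometry,
    FlowConditions,
    FlowField,
    cumulative_flux,
    dividing_streamline,
    n1_fields,
    sample_stream_width,
    solve_flow,
)
from .rheology import FluidSpec
from .sepmetrics import SeparationResult

__all__ = [
    "ParticleClass",
    "ForceModelParams",
    "Trajectory",
    "DeviceSimulation",
    "BLOOD_MIMIC_CLASSES",
    "elastic_force",
    "drag_force",
    "inertial_lift",
    "buoyancy",
    "virtual_mass_force",
    "migration_velocity",
    "rk4_path",
    "integrate_trajectory",
    "assign_outlet",
    "calibrate_module_length",
    "default_geometry",
    "simulate_device",
]


@dataclass(frozen=True)
class ParticleClass:
    """A particle population of fixed diameter and density.

    ``fluorophore`` is a metadata tag used by the synthetic cytometry-event
    generator; it does not influence the dynamics.
    """

    label: str
    diameter: float
    density: float = 1050.0  # kg/m^3, polystyrene; near-neutrally buoyant
    fluorophore: str = ""

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("particle diameter must be positive")
        if not self.density > 0:
            raise ValueError("particle density must be positive")

    @property
    def volume(self) -> float:
        """Particle volume V_p = pi*a^3/6 (m^3)."""
        return math.pi * self.diameter**3 / 6.0


#: The six characteristic blood-component sizes: WBC-, RBC-, PLT-, lEV-, mEV-
#: and sEV-scale particles.
BLOOD_MIMIC_CLASSES: tuple[ParticleClass, ...] = (
    ParticleClass("12um", 12e-6, fluorophore="none"),
    ParticleClass("7um", 7e-6, fluorophore="none"),
    ParticleClass("3um", 3e-6, fluorophore="PE"),
    ParticleClass("1um", 1e-6, fluorophore="red"),
    ParticleClass("500nm", 500e-9, fluorophore="yellow"),
    ParticleClass("100nm", 100e-9, fluorophore="blue"),
)


@dataclass(frozen=True)
class ForceModelParams:
    """Coefficients and toggles of the particle force model.

    ``elastic_sign=-1`` encodes the adopted convention that the elastic lift
    points toward decreasing N1 (centerline focusing); ``C_i`` has no
    published value and the inertial lift is negligible at these particle
    Reynolds numbers, so it defaults to off.
    """

    elastic_lift_coeff: float = 0.0184  # C_e
    inertial_lift_coeff: float = 0.0    # C_i (no published value)
    gravity: float = 9.81               # m/s^2
    elastic_sign: float = -1.0
    include_elastic: bool = True
    include_inertial_lift: bool = False
    include_buoyancy: bool = False
    include_virtual_mass: bool = True

    def __post_init__(self) -> None:
        if self.elastic_lift_coeff < 0:
            raise ValueError("elastic lift coefficient must be non-negative")
        if self.elastic_sign not in (-1.0, 1.0):
            raise ValueError("elastic_sign must be +/-1")


@dataclass
class Trajectory:
    """Time-stamped particle path through one module.

    ``truncated`` marks step-budget exhaustion before reaching the outlet
    cross-section (such particles are tallied as lost); ``wall_contact``
    marks that the wall-clearance clamp (a/2) engaged at least once.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    particle: ParticleClass
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None
    outlet: str | None = None
    truncated: bool = False
    wall_contact: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory timestamps must be strictly increasing")

    @property
    def final_position(self) -> tuple[float, float]:
        return float(self.x[-1]), float(self.y[-1])


# ---------------------------------------------------------------------------
# force models
# ---------------------------------------------------------------------------

def elastic_force(diameter: float, grad_n1, params: ForceModelParams):
    """Elastic lift F_e = sign * C_e * a^3 * grad(N1)  (vector, N)."""
    if not params.include_elastic:
        return np.zeros_like(np.asarray(grad_n1, dtype=float))
    return params.elastic_sign * params.elastic_lift_coeff * diameter**3 * np.asarray(grad_n1, dtype=float)


def drag_force(diameter: float, viscosity: float, u, v_p):
    """Stokes drag F_d = 3*pi*a*eta*(u - v_p)  (vector, N)."""
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    return 3.0 * math.pi * diameter * viscosity * (np.asarray(u, dtype=float) - np.asarray(v_p, dtype=float))

def inertial_lift(params: ForceModelParams, rho_f: float, u_max: float, diameter: float, width: float) -> float:
    """Inertial lift magnitude F_i = C_i*rho_f*u_max^2*a^4/w^2 (N); off by default."""
    if width <= 0:
        raise ValueError("channel width must be positive")
    if not params.include_inertial_lift:
        return 0.0
    return params.inertial_lift_coeff * rho_f * u_max**2 * diameter**4 / width**2


def buoyancy(rho_p: float, rho_f: float, volume: float, g: float) -> float:
    """Net gravity/buoyancy magnitude (rho_p - rho_f)*V_p*g (N).

    Zero for neutrally buoyant particles.  In the planar channel model
    gravity is normal to the flow plane, so this force never enters the 2D
    equation of motion unless explicitly toggled on (then applied along -y).
    """
    return (rho_p - rho_f) * volume * g


def virtual_mass_force(rho_f: float, volume: float, du_dt, dvp_dt):
    """Virtual-mass force 0.5*rho_f*V_p*(Du/Dt - dv_p/dt)  (vector, N).

    The relative-acceleration form; in the integrator the ``-dv_p/dt`` part
    is folded into the effective particle mass ``(rho_p + rho_f/2)*V_p``.
    """
    return 0.5 * rho_f * volume * (np.asarray(du_dt, dtype=float) - np.asarray(dvp_dt, dtype=float))


def migration_velocity(diameter: float, viscosity: float, grad_n1, params: ForceModelParams):
    """Overdamped lateral migration velocity (m/s).

    Drag balances the elastic lift: v_mig = sign*C_e*a^2*grad(N1)/(3*pi*eta),
    hence the a^2 size scaling of migration speed.
    """
    return elastic_force(diameter, grad_n1, params) / (3.0 * math.pi * diameter * viscosity)


# ---------------------------------------------------------------------------
# RK4 integration
# ---------------------------------------------------------------------------

def rk4_path(velocity: Callable, start: Sequence[float], dt: float, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical fixed-step RK4 advance of ``dx/dt = velocity(x)``.

    ``velocity`` maps an (..., 2) position array to an (..., 2) velocity.
    Returns (times, positions) including the initial state.  This is the
    reference path integrator; the gridded fast path in
    :func:`integrate_trajectory` reproduces it on interpolated fields.
    """
    pos = np.asarray(start, dtype=float)
    out = np.empty((n_steps + 1,) + pos.shape)
    out[0] = pos
    for k in range(n_steps):
        k1 = np.asarray(velocity(pos))
        k2 = np.asarray(velocity(pos + 0.5 * dt * k1))
        k3 = np.asarray(velocity(pos + 0.5 * dt * k2))
        k4 = np.asarray(velocity(pos + dt * k3))
        pos = pos + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[k + 1] = pos
    times = dt * np.arange(n_steps + 1)
    return times, out


def _advect_batch(wx, wy, inv_dx, inv_dy, nx, ny, xs, ys, dt, max_steps,
                  x_exit, y_lo, y_hi, stride, traj_x, traj_y, traj_n, status, wall_flag):
    """Advance all particles through one module (scalar loops; numba-jitted).

    ``wx, wy``: combined advection field (fluid velocity + class migration
    velocity) on the (ny, nx) grid.  Updates ``xs, ys`` in place; ``status``
    becomes 0 on outlet exit, stays 1 if the step budget runs out.  When
    ``traj_x`` has a positive row length, positions are recorded every
    ``stride`` steps until the row is full.
    """
    n = xs.shape[0]
    cap = traj_x.shape[1]
    for p in range(n):
        x = xs[p]
        y = ys[p]
        wall = False
        st = 1
        nrec = 0
        for step in range(max_steps):
            if cap > 0 and step % stride == 0 and nrec < cap:
                traj_x[p, nrec] = x
                traj_y[p, nrec] = y
                nrec += 1
            # RK4 stages on the bilinearly interpolated field
            ax = x
            ay = y
            k1x, k1y = _bilerp2(wx, wy, ax, ay, inv_dx, inv_dy, nx, ny)
            ax = x + 0.5 * dt * k1x
            ay = y + 0.5 * dt * k1y
            k2x, k2y = _bilerp2(wx, wy, ax, ay, inv_dx, inv_dy, nx, ny)
            ax = x + 0.5 * dt * k2x
            ay = y + 0.5 * dt * k2y
            k3x, k3y = _bilerp2(wx, wy, ax, ay, inv_dx, inv_dy, nx, ny)
            ax = x + dt * k3x
            ay = y + dt * k3y
            k4x, k4y = _bilerp2(wx, wy, ax, ay, inv_dx, inv_dy, nx, ny)
            x = x + (dt / 6.0) * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
            y = y + (dt / 6.0) * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
            if y < y_lo:
                y = y_lo
                wall = True
            elif y > y_hi:
                y = y_hi
                wall = True
            if x >= x_exit:
                x = x_exit
                st = 0
                break
        xs[p] = x
        ys[p] = y
        status[p] = st
        wall_flag[p] = wall
        traj_n[p] = nrec


def _bilerp2(fx, fy, x, y, inv_dx, inv_dy, nx, ny):
    """Bilinear interpolation of two (ny, nx) fields at physical (x, y)."""
    gx = x * inv_dx
    gy = y * inv_dy
    if gx < 0.0:
        gx = 0.0
    elif gx > nx - 1.000001:
        gx = nx - 1.000001
    if gy < 0.0:
        gy = 0.0
    elif gy > ny - 1.000001:
        gy = ny - 1.000001
    i = int(gx)
    j = int(gy)
    tx = gx - i
    ty = gy - j
    w00 = (1.0 - tx) * (1.0 - ty)
    w10 = tx * (1.0 - ty)
    w01 = (1.0 - tx) * ty
    w11 = tx * ty
    vx = w00 * fx[j, i] + w10 * fx[j, i + 1] + w01 * fx[j + 1, i] + w11 * fx[j + 1, i + 1]
    vy = w00 * fy[j, i] + w10 * fy[j, i + 1] + w01 * fy[j + 1, i] + w11 * fy[j + 1, i + 1]
    return vx, vy


try:  # JIT-compile the hot loop when numba is available; same code otherwise
    from numba import njit as _njit

    _bilerp2 = _njit(cache=True, inline="always")(_bilerp2)
    _advect_batch = _njit(cache=True)(_advect_batch)
except ImportError:  # pragma: no cover
    pass


def _class_advection_field(fld: FlowField, particle: ParticleClass, fluid: FluidSpec,
                           params: ForceModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Fluid velocity plus the class's overdamped migration velocity."""
    if fld.grad_n1 is None:
        n1_fields(fld, fluid)
    pref = params.elastic_sign * params.elastic_lift_coeff * particle.diameter**2 / (3.0 * math.pi * fluid.viscosity)
    if not params.include_elastic:
        pref = 0.0
    wx = fld.ux + pref * fld.grad_n1[0]
    wy = fld.uy + pref * fld.grad_n1[1]
    return np.ascontiguousarray(wx), np.ascontiguousarray(wy)


def _default_dt(fld: FlowField, speed_scale: float) -> float:
    """Fixed step: max displacement per step <= 0.2 grid cells."""
    cell = min(fld.dx, fld.dy)
    return 0.2 * cell / speed_scale


def advect_ensemble(
    fld: FlowField,
    particle: ParticleClass,
    y_starts: np.ndarray,
    fluid: FluidSpec,
    params: ForceModelParams,
    dt: float | None = None,
    max_steps: int = 10_000_000,
    n_snapshots: int = 0,
) -> dict:
    """Advect a batch of same-class particles from x=0 through the module.

    Returns a dict with final positions, exit status (0 exited, 1 truncated),
    wall-contact flags, the time step used and, when ``n_snapshots > 0``,
    subsampled paths.
    """
    wx, wy = _class_advection_field(fld, particle, fluid, params)
    speed = max(float(np.abs(wx).max()), float(np.abs(wy).max()), 1e-30)
    if dt is None:
        dt = _default_dt(fld, speed)
    clearance = particle.diameter / 2.0
    y_lo = min(clearance, fld.width / 2.0)
    y_hi = fld.width - y_lo
    xs = np.zeros_like(np.asarray(y_starts, dtype=float))
    ys = np.clip(np.asarray(y_starts, dtype=float), y_lo, y_hi)
    status = np.ones(xs.shape[0], dtype=np.int64)
    wall = np.zeros(xs.shape[0], dtype=np.bool_)
    traj_n = np.zeros(xs.shape[0], dtype=np.int64)
    cap = int(n_snapshots)
    # stride so a straight transit at the fastest speed fills the buffer
    est_steps = max(int(fld.length / (speed * dt)), 1)
    stride = max(1, est_steps // max(cap, 1)) if cap > 0 else 1
    traj_x = np.zeros((xs.shape[0], cap))
    traj_y = np.zeros((xs.shape[0], cap))
    _advect_batch(
        wx, wy, 1.0 / fld.dx, 1.0 / fld.dy, fld.x.size, fld.y.size,
        xs, ys, dt, int(max_steps), fld.length, y_lo, y_hi,
        stride, traj_x, traj_y, traj_n, status, wall,
    )
    return {
        "x": xs, "y": ys, "status": status, "wall_contact": wall,
        "dt": dt, "stride": stride,
        "traj_x": traj_x, "traj_y": traj_y, "traj_n": traj_n,
    }


def integrate_trajectory(
    fld: FlowField,
    particle: ParticleClass,
    start: Sequence[float],
    params: ForceModelParams,
    fluid: FluidSpec,
    mode: Literal["overdamped", "full_inertia"] = "overdamped",
    dt: float | None = None,
    max_steps: int = 10_000_000,
    n_snapshots: int = 400,
) -> Trajectory:
    """Integrate one particle path through a module with RK4.

    Overdamped mode advances position in the combined field
    ``u + v_mig``; full-inertia mode integrates the stiff
    position-velocity system (effective mass ``(rho_p + rho_f/2)*V_p``,
    elastic lift, Stokes drag and the fluid-acceleration half of the
    virtual-mass force) and is intended for validation at small steps.
    Terminates on reaching the outlet boundary or on budget exhaustion
    (``truncated`` flag).  Wall clearance a/2 is enforced by clamping with
    ``wall_contact`` set.
    """
    x0, y0 = float(start[0]), float(start[1])
    if not (0.0 <= x0 <= fld.length and 0.0 <= y0 <= fld.width):
        raise ValueError("start position outside the module domain")
    clearance = particle.diameter / 2.0
    if mode == "overdamped":
        if x0 != 0.0:
            raise ValueError("overdamped batch integration starts at the module entry x=0")
        out = advect_ensemble(
            fld, particle, np.array([y0]), fluid, params,
            dt=dt, max_steps=max_steps, n_snapshots=n_snapshots,
        )
        nrec = int(out["traj_n"][0])
        xs = np.append(out["traj_x"][0, :nrec], out["x"][0])
        ys = np.append(out["traj_y"][0, :nrec], out["y"][0])
        ts = out["dt"] * out["stride"] * np.arange(nrec + 1, dtype=float)
        # final sample is at the exit, not necessarily on the stride: nudge
        ts[-1] = max(ts[-1], ts[-2] + out["dt"]) if nrec >= 1 else 0.0
        return Trajectory(
            t=ts, x=xs, y=ys, particle=particle,
            truncated=bool(out["status"][0]), wall_contact=bool(out["wall_contact"][0]),
        )
    if mode != "full_inertia":
        raise ValueError(f"unknown integration mode {mode!r}")

    if fld.grad_n1 is None:
        n1_fields(fld, fluid)
    dux_dx = np.gradient(fld.ux, fld.dx, axis=1)
    dux_dy = np.gradient(fld.ux, fld.dy, axis=0)
    duy_dx = np.gradient(fld.uy, fld.dx, axis=1)
    duy_dy = np.gradient(fld.uy, fld.dy, axis=0)
    conv_x = fld.ux * dux_dx + fld.uy * dux_dy
    conv_y = fld.ux * duy_dx + fld.uy * duy_dy
    inv_dx, inv_dy = 1.0 / fld.dx, 1.0 / fld.dy
    nx, ny = fld.x.size, fld.y.size
    a = particle.diameter
    vol = particle.volume
    eff_mass = (particle.density + (0.5 * fluid.density if params.include_virtual_mass else 0.0)) * vol
    drag_coeff = 3.0 * math.pi * a * fluid.viscosity
    e_pref = (params.elastic_sign * params.elastic_lift_coeff * a**3) if params.include_elastic else 0.0
    vm_pref = 0.5 * fluid.density * vol if params.include_virtual_mass else 0.0
    f_buoy = -buoyancy(particle.density, fluid.density, vol, params.gravity) if params.include_buoyancy else 0.0
    f_lift = inertial_lift(params, fluid.density, fld.u_max, a, fld.width)

    def rhs(state):
        x, y, vx, vy = state
        ux, uy = _bilerp2(fld.ux, fld.uy, x, y, inv_dx, inv_dy, nx, ny)
        gx, gy = _bilerp2(fld.grad_n1[0], fld.grad_n1[1], x, y, inv_dx, inv_dy, nx, ny)
        cx, cy = _bilerp2(conv_x, conv_y, x, y, inv_dx, inv_dy, nx, ny)
        fx = e_pref * gx + drag_coeff * (ux - vx) + vm_pref * cx
        fy = e_pref * gy + drag_coeff * (uy - vy) + vm_pref * cy + f_buoy
        fy += f_lift * math.copysign(1.0, fld.width / 2.0 - y)
        return np.array([vx, vy, fx / eff_mass, fy / eff_mass])

    if dt is None:
        # resolve the velocity-relaxation time
        dt = 0.02 * eff_mass / drag_coeff
    u0x, u0y = _bilerp2(fld.ux, fld.uy, x0, y0, inv_dx, inv_dy, nx, ny)
    state = np.array([x0, y0, u0x, u0y])
    stride = max(1, max_steps // max(n_snapshots, 1))
    ts, xs, ys, vxs, vys = [0.0], [x0], [y0], [u0x], [u0y]
    truncated = True
    wall = False
    y_lo = min(clearance, fld.width / 2.0)
    for step in range(1, int(max_steps) + 1):
        k1 = rhs(state)
        k2 = rhs(state + 0.5 * dt * k1)
        k3 = rhs(state + 0.5 * dt * k2)
        k4 = rhs(state + dt * k3)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if state[1] < y_lo:
            state[1] = y_lo
            wall = True
        elif state[1] > fld.width - y_lo:
            state[1] = fld.width - y_lo
            wall = True
        exited = state[0] >= fld.length
        if step % stride == 0 or exited:
            ts.append(step * dt)
            xs.append(state[0])
            ys.append(state[1])
            vxs.append(state[2])
            vys.append(state[3])
        if exited:
            truncated = False
            break
    return Trajectory(
        t=np.array(ts), x=np.array(xs), y=np.array(ys), particle=particle,
        vx=np.array(vxs), vy=np.array(vys), truncated=truncated, wall_contact=wall,
    )


# ---------------------------------------------------------------------------
# outlet routing
# ---------------------------------------------------------------------------

def assign_outlet(
    traj_or_y: "Trajectory | float",
    dividing: tuple[float, float],
    central_label: str,
    side_label: str,
) -> str | None:
    """Assign a particle to an outlet from its final lateral position.

    ``dividing`` holds the two dividing-streamline y positions (lower, upper)
    at the assignment cross-section.  Final positions strictly between them
    go to the central outlet; positions exactly on a dividing streamline are
    assigned to the wall-side outlet (documented tie-break).  A truncated
    trajectory returns ``None`` (counted as lost).
    """
    if isinstance(traj_or_y, Trajectory):
        if traj_or_y.truncated:
            return None
        y = traj_or_y.final_position[1]
    else:
        y = float(traj_or_y)
    lower, upper = dividing
    return central_label if lower < y < upper else side_label


# ---------------------------------------------------------------------------
# geometry calibration and the full device simulation
# ---------------------------------------------------------------------------

def calibrate_module_length(
    width: float,
    u_max: float,
    fluid: FluidSpec,
    params: ForceModelParams,
    diameter: float,
    entry_distance: float | None = None,
    completion: float = 0.05,
) -> float:
    """Channel length for a particle class to complete its lateral migration.

    In a fully developed parabolic profile the overdamped lateral dynamics
    reduce to ``d(eta)/dx = -k*eta / u(eta)`` for the scaled centerline
    offset ``eta = 2*(w/2 - d)/w`` and migration rate
    ``k = 256*C_e*a^2*mu_p*lambda*u_max^2 / (3*pi*eta_f*w^4)``, which
    integrates in closed form to ``L = (G(eta_0) - G(eta_1)) * u_max / k``
    with ``G(eta) = ln(eta) - eta^2/2``.  Returns the smallest length that
    brings a particle from its worst-case entry (wall clearance a/2 by
    default) to within ``completion`` half-widths of the centerline.
    """
    if entry_distance is None:
        entry_distance = diameter / 2.0
    eta0 = 1.0 - 2.0 * entry_distance / width
    eta1 = completion
    if not 0.0 < eta1 < eta0 < 1.0:
        raise ValueError("entry position must lie between the wall and the completion band")
    k = (
        256.0 * params.elastic_lift_coeff * diameter**2
        * fluid.polymer_viscosity * fluid.relaxation_time * u_max**2
        / (3.0 * math.pi * fluid.viscosity * width**4)
    )
    g = lambda e: math.log(e) - 0.5 * e**2
    return (g(eta0) - g(eta1)) * u_max / k


def poiseuille_exit_distance(
    width: float,
    u_max: float,
    fluid: FluidSpec,
    params: ForceModelParams,
    diameter: float,
    entry_distance: float,
    length: float,
) -> float:
    """Closed-form overdamped exit distance from the wall in a parabolic profile.

    Inverts the same migration integral as :func:`calibrate_module_length`
    for a given channel length.  Saturates at the centerline.
    """
    eta0 = 1.0 - 2.0 * entry_distance / width
    if not 0.0 < eta0 < 1.0:
        raise ValueError("entry position must lie strictly between wall and centerline")
    k = (
        256.0 * params.elastic_lift_coeff * diameter**2
        * fluid.polymer_viscosity * fluid.relaxation_time * u_max**2
        / (3.0 * math.pi * fluid.viscosity * width**4)
    )
    g = lambda e: math.log(e) - 0.5 * e**2
    target = g(eta0) - k * length / u_max
    tiny = 1e-9
    if target <= g(tiny):
        return width / 2.0
    eta1 = brentq(lambda e: g(e) - target, tiny, eta0)
    return (1.0 - eta1) * width / 2.0


def default_geometry(
    fluid: FluidSpec | None = None,
    params: ForceModelParams | None = None,
    conditions: FlowConditions | None = None,
    slowest_module1: float = 3e-6,
    slowest_module2: float = 1e-6,
) -> DeviceGeometry:
    """Device geometry with lengths calibrated at the given operating point.

    Module lengths are the migration-completion lengths of the slowest class
    that must reach the centerline in each module: 3 um in the cell-depletion
    module (entering at its wall clearance a/2), 1 um in the sEV-isolation
    module (entering at its flux-remapped module-1 exit position, evaluated
    with the same closed-form migration integral on the parabolic profile).
    """
    from .flowfield import poiseuille_flux_fraction

    fluid = fluid or FluidSpec()
    params = params or ForceModelParams()
    conditions = conditions or FlowConditions()
    base = DeviceGeometry()
    w1, w2 = base.width_module1, base.width_module2
    u_max1 = 1.5 * conditions.total / (w1 * base.height)
    l1 = calibrate_module_length(w1, u_max1, fluid, params, slowest_module1)
    # where the slowest module-2 class exits module 1 and enters module 2
    exit1 = poiseuille_exit_distance(
        w1, u_max1, fluid, params, slowest_module2, slowest_module2 / 2.0, l1
    )
    side = 1.0 - base.central_fraction_module1
    flux_target = min(poiseuille_flux_fraction(exit1, w1) / side, 0.5)
    entry2 = brentq(
        lambda d: poiseuille_flux_fraction(d, w2) - flux_target, 0.0, w2 / 2.0, xtol=1e-12
    )
    q2 = conditions.total * side
    u_max2 = 1.5 * q2 / (w2 * base.height)
    l2 = calibrate_module_length(w2, u_max2, fluid, params, slowest_module2, entry_distance=entry2)
    return replace(base, length_module1=l1, length_module2=l2)


@dataclass
class DeviceSimulation:
    """Output of :func:`simulate_device`.

    ``result`` carries the per-class per-outlet tallies; ``particles`` one row
    per simulated particle (entry position, per-module exit positions, outlet);
    ``fields`` the two solved module flow fields.
    """

    result: SeparationResult
    particles: pd.DataFrame
    fields: tuple[FlowField, FlowField]
    dividing: dict[str, tuple[float, float]]


def _remap_flux_coordinate(y1: np.ndarray, fld1: FlowField, fld2: FlowField) -> np.ndarray:
    """Map module-1 exit positions to module-2 entry positions.

    The side streams of module 1 become the whole of module 2, so a particle
    keeps its cumulative flux from the nearer sidewall: F2(y') = F1(y).
    """
    f1 = cumulative_flux(fld1)
    f2 = cumulative_flux(fld2, x_station=0.0)
    total2 = float(f2(fld2.width))
    out = np.empty_like(y1)
    for i, y in enumerate(y1):
        mirrored = y > fld1.width / 2.0
        d = fld1.width - y if mirrored else y
        target = min(float(f1(d)), total2 / 2.0)
        dprime = brentq(lambda yy: f2(yy) - target, 0.0, fld2.width / 2.0, xtol=1e-12)
        out[i] = fld2.width - dprime if mirrored else dprime
    return out


def simulate_device(
    geometry: DeviceGeometry | None = None,
    conditions: FlowConditions | None = None,
    fluid: FluidSpec | None = None,
    params: ForceModelParams | None = None,
    classes: Sequence[ParticleClass] = BLOOD_MIMIC_CLASSES[2:],
    n_per_class: int = 100,
    seed: int = 0,
    ny: int = 41,
    nx: int = 201,
    solver_tol: float = 1e-8,
    max_steps: int = 10_000_000,
) -> DeviceSimulation:
    """Run the full two-module separation for an ensemble of particles.

    Particles enter module 1 in the wall-adjacent sample bands (uniform in
    cumulative flux, seeded RNG), migrate under the overdamped force balance,
    and are routed at the module exit by the dividing streamlines of the
    outlet flux fractions: module-1 central -> waste outlet O1; side
    survivors are remapped to module-2 entry positions preserving their
    cumulative-flux coordinate; module-2 side -> O3 (the sEV outlet), central
    -> O2.  Per class, assigned + lost = input.
    """
    from .synthdata import generate_particle_ensemble  # local import: no cycle at module load

    conditions = conditions or FlowConditions()
    fluid = fluid or FluidSpec()
    params = params or ForceModelParams()
    geometry = geometry or default_geometry(fluid, params, conditions)

    fld1 = solve_flow(geometry, conditions, fluid, module=1, ny=ny, nx=nx, tol=solver_tol)
    fld2 = solve_flow(geometry, conditions, fluid, module=2, ny=ny, nx=nx, tol=solver_tol)
    n1_fields(fld1, fluid)
    n1_fields(fld2, fluid)

    side_share_1 = (1.0 - geometry.central_fraction_module1) / 2.0
    div1 = dividing_streamline(fld1, side_share_1, wall="both")
    div1_y = (div1[0], fld1.width - div1[1])  # as y coordinates
    side_share_2 = geometry.side_fraction_module2 / 2.0
    div2 = dividing_streamline(fld2, side_share_2, wall="both")
    div2_y = (div2[0], fld2.width - div2[1])

    band = sample_stream_width(fld1, conditions)
    ensemble = generate_particle_ensemble(
        classes, n_per_class, fld1, band=band, seed=seed
    )

    records = []
    for cls in classes:
        sub = ensemble[ensemble["label"] == cls.label]
        y0 = sub["y0"].to_numpy()
        out1 = advect_ensemble(fld1, cls, y0, fluid, params, max_steps=max_steps)
        y1, st1 = out1["y"], out1["status"]
        outlet = np.full(y0.shape, "", dtype=object)
        for i in range(y0.size):
            if st1[i] != 0:
                outlet[i] = "lost"
            else:
                outlet[i] = assign_outlet(float(y1[i]), div1_y, "O1", "module2") or "lost"
        to_m2 = outlet == "module2"
        y2 = np.full(y0.shape, np.nan)
        if np.any(to_m2):
            y2_in = _remap_flux_coordinate(y1[to_m2], fld1, fld2)
            out2 = advect_ensemble(fld2, cls, y2_in, fluid, params, max_steps=max_steps)
            y2b, st2 = out2["y"], out2["status"]
            labels2 = np.full(y2b.shape, "", dtype=object)
            for i in range(y2b.size):
                if st2[i] != 0:
                    labels2[i] = "lost"
                else:
                    labels2[i] = assign_outlet(float(y2b[i]), div2_y, "O2", "O3") or "lost"
            outlet[to_m2] = labels2
            y2[to_m2] = y2b
        rec = pd.DataFrame({
            "label": cls.label,
            "diameter": sub["diameter"].to_numpy(),
            "y0": y0,
            "y_exit_module1": y1,
            "y_exit_module2": y2,
            "outlet": outlet,
            "wall_contact": out1["wall_contact"],
        })
        records.append(rec)
    particles = pd.concat(records, ignore_index=True)

    counts = {
        cls.label: {
            o: int(((particles["label"] == cls.label) & (particles["outlet"] == o)).sum())
            for o in ("O1", "O2", "O3")
        }
        for cls in classes
    }
    lost = {
        cls.label: int(((particles["label"] == cls.label) & (particles["outlet"] == "lost")).sum())
        for cls in classes
    }
    result = SeparationResult(counts=counts, lost=lost)
    return DeviceSimulation(
        result=result,
        particles=particles,
        fields=(fld1, fld2),
        dividing={"module1": div1_y, "module2": div2_y},
    )
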