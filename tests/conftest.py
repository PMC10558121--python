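"""Shared fixtures: analytic reference fields and one session device run."""

from __future__ import annotations

import numpy as np
import pytest

import vesiflow as vf
from vesiflow.flowfield import FlowField


def make_poiseuille_field(
    width: float = 20e-6,
    length: float = 3e-4,
    u_mean: float = 1.0,
    ny: int = 81,
    nx: int = 41,
    height: float = 55e-6,
) -> FlowField:
    """Exact plane-Poiseuille FlowField (analytic profile, no solver)."""
    y = np.linspace(0.0, width, ny)
    x = np.linspace(0.0, length, nx)
    s = y / width
    u = 6.0 * u_mean * s * (1.0 - s)
    psi = u_mean * width * (3.0 * s**2 - 2.0 * s**3)
    zeros = np.zeros((ny, nx))
    return FlowField(
        x=x, y=y,
        ux=np.repeat(u[:, None], nx, axis=1),
        uy=zeros.copy(),
        psi=np.repeat(psi[:, None], nx, axis=1),
        p=zeros.copy(),
        width=width, length=length, height=height,
        flow_rate=u_mean * width * height,
    )


def make_uniform_field(
    speed: float = 0.5,
    width: float = 20e-6,
    length: float = 1e-4,
    ny: int = 41,
    nx: int = 21,
) -> FlowField:
    """Uniform-translation FlowField (plug flow, zero shear)."""
    y = np.linspace(0.0, width, ny)
    x = np.linspace(0.0, length, nx)
    ones = np.ones((ny, nx))
    return FlowField(
        x=x, y=y,
        ux=speed * ones,
        uy=np.zeros_like(ones),
        psi=speed * np.repeat(y[:, None], nx, axis=1),
        p=np.zeros_like(ones),
        width=width, length=length, height=55e-6,
        flow_rate=speed * width * 55e-6,
    )


@pytest.fixture(scope="session")
def fluid() -> vf.FluidSpec:
    return vf.FluidSpec()


@pytest.fixture(scope="session")
def params() -> vf.ForceModelParams:
    return vf.ForceModelParams()


@pytest.fixture(scope="session")
def geometry() -> vf.DeviceGeometry:
    return vf.default_geometry()


@pytest.fixture(scope="session")
def conditions() -> vf.FlowConditions:
    return vf.FlowConditions()


@pytest.fixture(scope="session")
def module1_field(geometry, conditions, fluid) -> FlowField:
    fld = vf.solve_flow(geometry, conditions, fluid, module=1)
    vf.n1_fields(fld, fluid)
    return fld


@pytest.fixture(scope="session")
def module2_field(geometry, conditions, fluid) -> FlowField:
    fld = vf.solve_flow(geometry, conditions, fluid, module=2)
    vf.n1_fields(fld, fluid)
    return fld


@pytest.fixture(scope="session")
def device_sim(geometry) -> vf.DeviceSimulation:
    """One moderately sized device simulation reused across routing tests."""
    return vf.simulate_device(geometry=geometry, n_per_class=60, seed=11)
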