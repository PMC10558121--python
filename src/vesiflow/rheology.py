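"""Carrier-fluid rheology and the dimensionless numbers of viscoelastic focusing.

The carrier fluid is a dilute solution of high-molecular-weight poly(ethylene
oxide) (PEO) in PBS.  At the concentrations used for vesicle sorting its shear
viscosity is constant over the relevant shear-rate range, so the velocity field
is Newtonian while the elastic stresses follow the Oldroyd-B constitutive
model, whose first normal stress difference is

    N1 = 2 * mu_p * lam * gamma_dot**2

with ``mu_p`` the polymeric contribution to the viscosity and ``lam`` the fluid
relaxation time.  Gradients of N1 drive size-dependent lateral particle
migration (see :mod:`vesiflow.dynamics`).

This module holds the fluid parameterization (:class:`FluidSpec`) and the
scalar diagnostics used to justify the modelling assumptions: the polymer
diffusion coefficient (Stokes-Einstein), the Peclet number (advection vs
polymer diffusion), and the channel / particle Reynolds numbers (inertia vs
viscosity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "BOLTZMANN",
    "FluidSpec",
    "DimensionlessReport",
    "stokes_einstein_diffusivity",
    "first_normal_stress",
    "peclet",
    "channel_reynolds",
    "particle_reynolds",
    "build_fluid_spec",
    "dimensionless_report",
]

#: Boltzmann constant (J/K).
BOLTZMANN = 1.380649e-23

# Default carrier fluid: average of the 0.1% and 0.15% w/v 600-kDa PEO
# solutions used in the sample and guide streams.
_DEFAULTS = {
    "density": 1000.0,           # kg/m^3
    "viscosity": 1.43e-3,        # Pa.s, average total viscosity
    "polymer_viscosity": 0.41e-3,  # Pa.s, polymeric contribution mu_p
    "relaxation_time": 0.55e-3,  # s
    "gyration_radius": 48e-9,    # m, 600-kDa PEO coil
    "solvent_viscosity": 1.0e-3,  # Pa.s, water at room temperature
    "temperature": 293.0,        # K, room temperature
    "peo_concentration": 0.00125,  # w/v fraction, metadata (mean of 0.1/0.15%)
}

#: Concentration (w/v fraction) -> total viscosity (Pa.s) anchors.  Only the
#: measured average of the two working concentrations is pre-loaded; extend via
#: :func:`build_fluid_spec` config for other solutions.
VISCOSITY_TABLE: dict[float, float] = {0.00125: 1.43e-3}


@dataclass(frozen=True)
class FluidSpec:
    """Viscoelastic carrier-fluid parameters.

    Parameters
    ----------
    density : float
        Fluid density rho_f (kg/m^3).
    viscosity : float
        Total dynamic viscosity eta (Pa.s).
    polymer_viscosity : float
        Polymeric viscosity contribution mu_p (Pa.s); must be < viscosity.
    relaxation_time : float
        Oldroyd-B relaxation time lambda (s).
    gyration_radius : float
        Polymer coil gyration radius r_g (m), sets the polymer diffusivity.
    solvent_viscosity : float
        Solvent (water/PBS) viscosity eta_s (Pa.s) used in Stokes-Einstein.
    temperature : float
        Absolute temperature (K); must lie in [273, 320].
    peo_concentration : float
        PEO mass concentration (w/v fraction).  Metadata only.
    """

    density: float = _DEFAULTS["density"]
    viscosity: float = _DEFAULTS["viscosity"]
    polymer_viscosity: float = _DEFAULTS["polymer_viscosity"]
    relaxation_time: float = _DEFAULTS["relaxation_time"]
    gyration_radius: float = _DEFAULTS["gyration_radius"]
    solvent_viscosity: float = _DEFAULTS["solvent_viscosity"]
    temperature: float = _DEFAULTS["temperature"]
    peo_concentration: float = _DEFAULTS["peo_concentration"]

    def __post_init__(self) -> None:
        for name in (
            "density",
            "viscosity",
            "polymer_viscosity",
            "relaxation_time",
            "gyration_radius",
            "solvent_viscosity",
            "temperature",
        ):
            value = getattr(self, name)
            if not (value > 0.0 and math.isfinite(value)):
                raise ValueError(f"FluidSpec.{name} must be strictly positive, got {value!r}")
        if self.peo_concentration < 0:
            raise ValueError("peo_concentration must be non-negative")
        if self.polymer_viscosity >= self.viscosity:
            raise ValueError(
                "polymeric viscosity mu_p must be smaller than the total viscosity eta "
                f"(got mu_p={self.polymer_viscosity}, eta={self.viscosity})"
            )
        if not 273.0 <= self.temperature <= 320.0:
            raise ValueError(f"temperature {self.temperature} K outside the liquid-water band [273, 320] K")

    @property
    def diffusivity(self) -> float:
        """Polymer diffusion coefficient D0 (m^2/s) via Stokes-Einstein."""
        return stokes_einstein_diffusivity(
            self.gyration_radius, self.temperature, self.solvent_viscosity
        )


@dataclass(frozen=True)
class DimensionlessReport:
    """Dimensionless diagnostics at a given channel operating point."""

    diffusivity: float
    peclet: float
    channel_reynolds: float
    particle_reynolds: dict[str, float]
    u_max: float
    width: float

    def __post_init__(self) -> None:
        values = [self.diffusivity, self.peclet, self.channel_reynolds, self.u_max, self.width]
        values += list(self.particle_reynolds.values())
        if any(v < 0 for v in values):
            raise ValueError("all dimensionless-report values must be non-negative")


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0.0 and math.isfinite(value)):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def stokes_einstein_diffusivity(r_g: float, temperature: float, solvent_viscosity: float) -> float:
    """Diffusion coefficient of a coil of gyration radius ``r_g``.

    D0 = k_B * T / (6 * pi * eta_s * r_g).
    """
    _require_positive(r_g=r_g, temperature=temperature, solvent_viscosity=solvent_viscosity)
    return BOLTZMANN * temperature / (6.0 * math.pi * solvent_viscosity * r_g)


def first_normal_stress(gamma_dot, polymer_viscosity: float, relaxation_time: float):
    """Oldroyd-B first normal stress difference N1 = 2*mu_p*lam*gamma_dot^2.

    Accepts scalar or array shear rates; even and non-negative in gamma_dot.
    """
    if polymer_viscosity < 0 or relaxation_time < 0:
        raise ValueError("polymer viscosity and relaxation time must be non-negative")
    return 2.0 * polymer_viscosity * relaxation_time * gamma_dot**2


def peclet(u_max: float, width: float, diffusivity: float) -> float:
    """Peclet number Pe = u_max * w / D0 (advection vs polymer diffusion)."""
    _require_positive(diffusivity=diffusivity)
    if u_max < 0 or width < 0:
        raise ValueError("u_max and width must be non-negative")
    return u_max * width / diffusivity


def channel_reynolds(density: float, u_max: float, width: float, viscosity: float) -> float:
    """Channel Reynolds number R = rho * u_max * w / eta."""
    _require_positive(viscosity=viscosity)
    if u_max < 0 or width < 0 or density < 0:
        raise ValueError("density, u_max and width must be non-negative")
    return density * u_max * width / viscosity


def particle_reynolds(channel_re: float, diameter: float, width: float) -> float:
    """Particle Reynolds number R_P = R * (a/w)^2."""
    _require_positive(width=width, diameter=diameter)
    if channel_re < 0:
        raise ValueError("channel Reynolds number must be non-negative")
    return channel_re * (diameter / width) ** 2


def build_fluid_spec(config: Mapping[str, float] | None = None) -> FluidSpec:
    """Build a :class:`FluidSpec` from a configuration mapping.

    Unspecified fields take the default working-fluid values.  If the config
    supplies only ``peo_concentration`` and that concentration has an entry in
    :data:`VISCOSITY_TABLE`, the total viscosity is looked up from the table.
    Explicit values always win.  Invalid or contradictory values raise
    ``ValueError`` via :class:`FluidSpec` validation.
    """
    config = dict(config or {})
    unknown = set(config) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown fluid parameters: {sorted(unknown)}")
    if "viscosity" not in config and "peo_concentration" in config:
        conc = config["peo_concentration"]
        if conc in VISCOSITY_TABLE:
            config["viscosity"] = VISCOSITY_TABLE[conc]
    merged = {**_DEFAULTS, **config}
    return FluidSpec(**merged)


def dimensionless_report(
    fluid: FluidSpec,
    u_max: float,
    width: float,
    diameters: Mapping[str, float] | None = None,
) -> DimensionlessReport:
    """Assemble the standard dimensionless diagnostics for an operating point.

    Parameters
    ----------
    fluid : FluidSpec
        Carrier fluid.
    u_max : float
        Maximum streamwise velocity in the channel (m/s).
    width : float
        Channel width (m).
    diameters : mapping, optional
        Particle class label -> diameter (m) for per-class particle Reynolds
        numbers.
    """
    d0 = fluid.diffusivity
    re = channel_reynolds(fluid.density, u_max, width, fluid.viscosity)
    rp = {
        label: particle_reynolds(re, a, width) for label, a in (diameters or {}).items()
    }
    return DimensionlessReport(
        diffusivity=d0,
        peclet=peclet(u_max, width, d0),
        channel_reynolds=re,
        particle_reynolds=rp,
        u_max=u_max,
        width=width,
    )
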