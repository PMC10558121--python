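"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Real inputs to this kind of analysis are blood samples, cytometer event lists
and nanoparticle-tracking size measurements; none can ship with a code
package.  This module generates stand-ins with the documented statistical
structure instead:

* particle ensembles entering the device in the wall-pinched sample bands
  (positions uniform in cumulative flux; diameters per class distribution,
  point mass for calibration beads, log-normal for vesicle populations);
* two-parameter (side scatter x fluorescence) event clouds per class,
  log-normal in intensity, with the true generating label retained so that
  gating can be scored against ground truth;
* log-normal diameter mixtures for the sEV-rich and larger-EV outlet
  streams, calibrated so their population means are 97 nm and 143 nm;
* blood-sample compositions under buffer dilution with an sEV spike.

Every generator is a pure function of (specification, seed): fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dynamics import ParticleClass
from .flowfield import FlowField, cumulative_flux
from .sepmetrics import SizeDistribution

__all__ = [
    "BloodSampleSpec",
    "EventCloud",
    "ClassMixtureSpec",
    "DEFAULT_EVENT_CLOUDS",
    "SPIKED_BLOOD_COMPOSITION",
    "SIZE_PRESETS",
    "generate_particle_ensemble",
    "generate_event_table",
    "generate_size_sample",
    "generate_blood_composition",
]


@dataclass(frozen=True)
class BloodSampleSpec:
    """Whole-blood composition, spike level and buffer dilution.

    Default per-class concentrations are physiological-typical stand-ins
    (RBC 5e9, PLT 3e8, WBC 7e6 per mL) -- representative textbook values,
    fully configurable.  ``dilution_ratio`` is buffer:blood by volume and the
    sEV spike is expressed per mL of whole blood (added before dilution).
    """

    dilution_ratio: float = 4.0
    concentrations_per_ml: Mapping[str, float] = field(
        default_factory=lambda: {"RBC": 5e9, "PLT": 3e8, "WBC": 7e6}
    )
    spiked_sev_per_ml: float = 5e8

    def __post_init__(self) -> None:
        if self.dilution_ratio < 0:
            raise ValueError("dilution ratio must be non-negative")
        if self.spiked_sev_per_ml < 0 or any(c < 0 for c in self.concentrations_per_ml.values()):
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class EventCloud:
    """Log-normal intensity cloud of one class in (VSSC, FITC) space.

    Means and sigmas are in log10 intensity units.
    """

    log_vssc_mean: float
    log_fitc_mean: float
    log_sigma: float = 0.12

    def __post_init__(self) -> None:
        if self.log_sigma <= 0:
            raise ValueError("cloud sigma must be positive")


@dataclass(frozen=True)
class ClassMixtureSpec:
    """Mixing fractions plus per-class diameter and event-cloud parameters."""

    fractions: Mapping[str, float]
    clouds: Mapping[str, EventCloud]
    size_distributions: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    """Optional per-class (median_diameter_m, geometric_sigma) log-normals;
    classes without an entry are point masses."""

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"mixing fractions must sum to 1, got {total}")
        if set(self.fractions) - set(self.clouds):
            raise ValueError("every mixture class needs an event cloud")
        for label, (_, gsd) in self.size_distributions.items():
            if gsd <= 1.0:
                raise ValueError(f"geometric sigma for {label} must exceed 1")


#: Well-separated default clouds for the spiked-blood experiment classes
#: (>= 6 cluster sigma apart in log space).
DEFAULT_EVENT_CLOUDS: dict[str, EventCloud] = {
    "blood_cells": EventCloud(log_vssc_mean=5.0, log_fitc_mean=2.0),
    "sEV": EventCloud(log_vssc_mean=3.0, log_fitc_mean=4.0),
    "other": EventCloud(log_vssc_mean=2.0, log_fitc_mean=1.0),
}

#: Composition of the spiked whole-blood sample at the device inlet:
#: 9.7% labelled sEVs, 88.6% blood cells, the remainder other debris.
SPIKED_BLOOD_COMPOSITION: dict[str, float] = {"sEV": 0.097, "blood_cells": 0.886, "other": 0.017}


def _lognormal_components(mean_gsd_weights: Sequence[tuple[float, float, float]]):
    """(weight, mean, gsd) component list -> (weights, medians, sigmas)."""
    w = np.array([c[0] for c in mean_gsd_weights], dtype=float)
    mean = np.array([c[1] for c in mean_gsd_weights], dtype=float)
    gsd = np.array([c[2] for c in mean_gsd_weights], dtype=float)
    sigma = np.log(gsd)
    median = mean / np.exp(0.5 * sigma**2)  # so each component has the stated mean
    return w / w.sum(), median, sigma


#: Outlet-stream size presets as (weight, component mean nm, geometric sigma)
#: mixtures; population means are 97 nm (sEV outlet) and 143 nm (larger-EV
#: outlet) by construction.
SIZE_PRESETS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "O3-like": ((1.0, 97.0, 1.35),),
    "O2-like": ((0.7, 97.0, 1.35), (0.3, 250.3333333333333, 1.35)),
}


def generate_particle_ensemble(
    classes: Sequence[ParticleClass],
    n_per_class: int,
    fld: FlowField,
    band: tuple[float, float],
    seed: int = 0,
    size_distributions: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Entry ensemble: diameters and lateral positions in the sample bands.

    Positions are uniform in cumulative flux within the wall-adjacent bands
    (widths ``band = (lower, upper)``), half of the ensemble along each wall,
    mirroring how a pinched sample stream distributes particles across its
    streamlines.  Diameters are the class diameter, or log-normal when the
    class has an entry in ``size_distributions`` (median, geometric sigma).
    Reproducible for a fixed seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    lo_band, hi_band = band
    if lo_band <= 0 and hi_band <= 0:
        raise ValueError("sample-stream band is empty")
    rng = np.random.default_rng(seed)
    fcum = cumulative_flux(fld, x_station=0.0)
    total = float(fcum(fld.width))

    def invert_lower(target: float) -> float:
        return brentq(lambda yy: float(fcum(yy)) - target, 0.0, fld.width, xtol=1e-12)

    flux_lo = float(fcum(lo_band)) if lo_band > 0 else 0.0
    flux_hi = (total - float(fcum(fld.width - hi_band))) if hi_band > 0 else 0.0

    frames = []
    for cls in classes:
        child = np.random.default_rng(rng.integers(0, 2**31 - 1))
        on_lower = child.random(n_per_class) < flux_lo / max(flux_lo + flux_hi, 1e-300)
        q = child.random(n_per_class)
        y0 = np.empty(n_per_class)
        for i in range(n_per_class):
            if on_lower[i]:
                y0[i] = invert_lower(q[i] * flux_lo)
            else:
                y0[i] = fld.width - invert_lower(q[i] * flux_hi)
        dist = (size_distributions or {}).get(cls.label)
        if dist is None:
            diam = np.full(n_per_class, cls.diameter)
        else:
            median, gsd = dist
            diam = median * np.exp(math.log(gsd) * child.standard_normal(n_per_class))
        frames.append(pd.DataFrame({"label": cls.label, "diameter": diam, "y0": y0, "wall": np.where(on_lower, "lower", "upper")}))
    return pd.concat(frames, ignore_index=True)


def generate_event_table(
    composition: Mapping[str, float] | None = None,
    clouds: Mapping[str, EventCloud] | None = None,
    n_events: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic two-parameter cytometry events with ground-truth labels.

    Class counts are a multinomial draw from ``composition`` (default: the
    spiked-blood inlet composition); intensities are log-normal around each
    class's cloud center.  Columns: ``vssc``, ``fitc``, ``label``.
    """
    composition = dict(composition or SPIKED_BLOOD_COMPOSITION)
    clouds = dict(clouds or DEFAULT_EVENT_CLOUDS)
    total = sum(composition.values())
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"composition fractions must sum to 1, got {total}")
    missing = set(composition) - set(clouds)
    if missing:
        raise ValueError(f"no event cloud for classes {sorted(missing)}")
    rng = np.random.default_rng(seed)
    labels = list(composition)
    counts = rng.multinomial(n_events, [composition[c] for c in labels])
    rows = []
    for label, count in zip(labels, counts):
        cloud = clouds[label]
        vssc = 10.0 ** (cloud.log_vssc_mean + cloud.log_sigma * rng.standard_normal(count))
        fitc = 10.0 ** (cloud.log_fitc_mean + cloud.log_sigma * rng.standard_normal(count))
        rows.append(pd.DataFrame({"vssc": vssc, "fitc": fitc, "label": label}))
    events = pd.concat(rows, ignore_index=True)
    return events.sample(frac=1.0, random_state=np.random.RandomState(seed)).reset_index(drop=True)


def generate_size_sample(
    preset: str | Sequence[tuple[float, float, float]] = "O3-like",
    n: int = 10_000,
    seed: int = 0,
    concentration_per_ml: float = 1e8,
    dilution_factor: float = 1.0,
) -> SizeDistribution:
    """Log-normal mixture diameter sample emulating an NTA measurement.

    ``preset`` is either a named outlet preset ("O3-like" mean 97 nm,
    "O2-like" mean 143 nm) or an explicit component list of
    (weight, component mean nm, geometric sigma).  The sample mean converges
    to the mixture mean as n grows.
    """
    if n < 1:
        raise ValueError("sample size must be at least 1")
    components = SIZE_PRESETS[preset] if isinstance(preset, str) else tuple(preset)
    weights, medians, sigmas = _lognormal_components(components)
    rng = np.random.default_rng(seed)
    which = rng.choice(len(weights), size=n, p=weights)
    diam = medians[which] * np.exp(sigmas[which] * rng.standard_normal(n))
    return SizeDistribution(
        diameters_nm=diam,
        concentration_per_ml=concentration_per_ml,
        dilution_factor=dilution_factor,
    )


def generate_blood_composition(spec: BloodSampleSpec, seed: int | None = None) -> dict[str, float]:
    """Per-class concentrations after spiking and buffer dilution.

    The sEV spike is added to whole blood first; every concentration is then
    divided by (dilution_ratio + 1).  Deterministic (the seed parameter is
    accepted for generator-API symmetry).
    """
    gamma = spec.dilution_ratio
    out = {label: c / (gamma + 1.0) for label, c in spec.concentrations_per_ml.items()}
    if spec.spiked_sev_per_ml > 0:
        out["sEV"] = out.get("sEV", 0.0) + spec.spiked_sev_per_ml / (gamma + 1.0)
    return out
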