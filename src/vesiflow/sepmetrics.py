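"""Separation-performance metrics, cytometry-style gating, NTA summaries.

Metric definitions (per-class, per-outlet, on integer event counts):

purity
    target-class count at an outlet / total count at that outlet.
recovery
    target count at its designated outlet / target input count
    (loss-including: particles lost in the device lower it).
separation efficiency
    target count at the outlet / total target count collected across all
    outlets (loss-excluding: equals recovery when nothing is lost, and is
    never smaller than it).

Event gating mirrors two-parameter flow-cytometry analysis: events are points
in (side scatter, fluorescence) intensity space, gates are rectangles or
convex polygons in log10-intensity space, and each event lands in at most one
gate.  NTA-style summaries reduce a sample of hydrodynamic diameters to the
mean, modal bin (5-nm bins by default) and cumulative distribution, with the
particle concentration rescaled by the measurement dilution factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "MetricUndefinedError",
    "SeparationResult",
    "SizeDistribution",
    "NTASummary",
    "GatingResult",
    "EVENT_COLUMNS",
    "validate_event_table",
    "purity",
    "recovery",
    "separation_efficiency",
    "make_gate",
    "gate_events",
    "nta_summary",
]

#: Required columns of an event table: violet side scatter, fluorescence,
#: and the generating (true) class label for synthetic data.
EVENT_COLUMNS = ("vssc", "fitc", "label")


class MetricUndefinedError(ValueError):
    """A metric's denominator is empty (no events to divide by)."""


@dataclass(frozen=True)
class SeparationResult:
    """Per-class particle tallies over the device outlets.

    ``counts[class][outlet]`` are collected counts, ``lost[class]`` the
    particles that never reached an assignment cross-section.  Input counts
    are the conserved sum; supplying ``inputs`` explicitly turns conservation
    into a checked invariant.
    """

    counts: Mapping[str, Mapping[str, int]]
    lost: Mapping[str, int] = field(default_factory=dict)
    inputs: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        for label, row in self.counts.items():
            for outlet, c in row.items():
                if int(c) != c or c < 0:
                    raise ValueError(f"count for {label}@{outlet} must be a non-negative integer")
            if self.lost.get(label, 0) < 0:
                raise ValueError(f"lost count for {label} must be non-negative")
        if self.inputs is not None:
            for label in self.counts:
                total = sum(self.counts[label].values()) + self.lost.get(label, 0)
                if total != self.inputs.get(label, 0):
                    raise ValueError(
                        f"conservation violated for {label}: outlets+lost={total} "
                        f"!= input={self.inputs.get(label, 0)}"
                    )

    @property
    def classes(self) -> list[str]:
        return list(self.counts)

    @property
    def outlets(self) -> list[str]:
        names: list[str] = []
        for row in self.counts.values():
            for o in row:
                if o not in names:
                    names.append(o)
        return names

    def input_count(self, label: str) -> int:
        if self.inputs is not None:
            return int(self.inputs[label])
        return sum(self.counts[label].values()) + int(self.lost.get(label, 0))

    def outlet_total(self, outlet: str) -> int:
        return sum(int(row.get(outlet, 0)) for row in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        """class x outlet count table (with a ``lost`` column)."""
        df = pd.DataFrame(self.counts).T.fillna(0).astype(int)
        df["lost"] = [int(self.lost.get(label, 0)) for label in df.index]
        return df


def purity(result: "SeparationResult | Mapping[str, int]", outlet: str | None, target: str) -> float:
    """Fraction of the target class among all particles at an outlet.

    ``result`` may be a :class:`SeparationResult` (then ``outlet`` selects the
    column) or a plain class->count composition for a single outlet.
    """
    if isinstance(result, SeparationResult):
        if outlet is None:
            raise ValueError("an outlet must be named when passing a SeparationResult")
        comp = {label: result.counts[label].get(outlet, 0) for label in result.classes}
    else:
        comp = dict(result)
    total = sum(comp.values())
    if total <= 0:
        raise MetricUndefinedError(f"no particles at outlet {outlet!r}; purity undefined")
    return comp.get(target, 0) / total


def recovery(result: SeparationResult, outlet: str, target: str) -> float:
    """Fraction of input target particles collected at the designated outlet."""
    n_in = result.input_count(target)
    if n_in <= 0:
        raise MetricUndefinedError(f"no input particles of class {target!r}; recovery undefined")
    return result.counts[target].get(outlet, 0) / n_in


def separation_efficiency(result: SeparationResult, outlet: str, target: str) -> float:
    """Fraction of collected target particles that exit at the designated outlet."""
    collected = sum(result.counts[target].values())
    if collected <= 0:
        raise MetricUndefinedError(f"no collected particles of class {target!r}; efficiency undefined")
    return result.counts[target].get(outlet, 0) / collected


# ---------------------------------------------------------------------------
# event gating
# ---------------------------------------------------------------------------

def validate_event_table(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("vssc", "fitc") if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    if len(events) and ((events["vssc"] < 0).any() or (events["fitc"] < 0).any()):
        raise ValueError("event intensities must be non-negative")
    return events


def make_gate(region) -> shapely.Geometry:
    """Build a gate polygon in log10-intensity space.

    ``region`` is either ``((x_lo, x_hi), (y_lo, y_hi))`` for a rectangle or a
    sequence of (x, y) vertices for a convex polygon, with x = log10(VSSC)
    and y = log10(FITC).
    """
    if isinstance(region, shapely.Geometry):
        poly = region
    else:
        region = list(region)
        if len(region) == 2:  # ((x_lo, x_hi), (y_lo, y_hi)) rectangle
            (x0, x1), (y0, y1) = region
            poly = shapely.box(x0, y0, x1, y1)
        else:  # vertex list
            poly = shapely.Polygon(region)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("gate region must be a valid polygon with positive area")
    return poly


@dataclass(frozen=True)
class GatingResult:
    counts: dict[str, int]
    composition: dict[str, float]
    ungated: int
    assignments: pd.Series

    @property
    def total(self) -> int:
        return int(self.assignments.size)


def gate_events(events: pd.DataFrame, gates: Mapping[str, object]) -> GatingResult:
    """Assign events to named gates in log10(VSSC) x log10(FITC) space.

    Gates must be pairwise non-overlapping (touching boundaries allowed), so
    every event lands in at most one gate; events outside all gates, or with
    a non-positive intensity (no logarithm), are counted as ungated.
    Composition fractions are per-gate counts over all events and sum to <= 1.
    """
    validate_event_table(events)
    polys = {name: make_gate(region) for name, region in gates.items()}
    names = list(polys)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = polys[a].intersection(polys[b])
            if inter.area > 1e-12 * min(polys[a].area, polys[b].area):
                raise ValueError(f"gates {a!r} and {b!r} overlap")
    n = len(events)
    assigned = pd.Series(np.full(n, "", dtype=object), index=events.index, name="gate")
    if n:
        positive = (events["vssc"].to_numpy() > 0) & (events["fitc"].to_numpy() > 0)
        x = np.where(positive, np.log10(np.where(positive, events["vssc"].to_numpy(), 1.0)), np.nan)
        y = np.where(positive, np.log10(np.where(positive, events["fitc"].to_numpy(), 1.0)), np.nan)
        taken = np.zeros(n, dtype=bool)
        for name, poly in polys.items():
            inside = np.zeros(n, dtype=bool)
            inside[positive] = shapely.contains_xy(poly, x[positive], y[positive]) | shapely.intersects_xy(poly, x[positive], y[positive])
            inside &= ~taken
            assigned.iloc[np.flatnonzero(inside)] = name
            taken |= inside
    counts = {name: int((assigned == name).sum()) for name in polys}
    ungated = n - sum(counts.values())
    composition = {name: (c / n if n else 0.0) for name, c in counts.items()}
    return GatingResult(counts=counts, composition=composition, ungated=ungated, assignments=assigned)


# ---------------------------------------------------------------------------
# NTA-style size summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SizeDistribution:
    """A sample of hydrodynamic diameters (nm) with its concentration scale."""

    diameters_nm: np.ndarray
    concentration_per_ml: float = 0.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_nm, dtype=float)
        object.__setattr__(self, "diameters_nm", d)
        if d.size and (d <= 0).any():
            raise ValueError("diameters must be positive")
        if self.concentration_per_ml < 0 or self.dilution_factor < 0:
            raise ValueError("concentration and dilution factor must be non-negative")


@dataclass(frozen=True)
class NTASummary:
    mean_nm: float
    mode_nm: float
    bin_edges_nm: np.ndarray
    bin_counts: np.ndarray
    cumulative: np.ndarray
    concentration_per_ml: float


def nta_summary(dist: SizeDistribution, bin_width_nm: float = 5.0) -> NTASummary:
    """Summarize a diameter sample the way tracking-analysis software does.

    Histogram with fixed-width bins (5 nm default), arithmetic-mean diameter,
    modal bin center, the cumulative distribution at the bin edges
    (monotone, reaching 1), and the sample concentration rescaled by the
    dilution factor.
    """
    d = dist.diameters_nm
    if d.size == 0:
        raise MetricUndefinedError("empty size sample; summary undefined")
    if bin_width_nm <= 0:
        raise ValueError("bin width must be positive")
    lo = bin_width_nm * np.floor(d.min() / bin_width_nm)
    hi = bin_width_nm * np.ceil(d.max() / bin_width_nm)
    if hi <= lo:
        hi = lo + bin_width_nm
    edges = np.arange(lo, hi + 0.5 * bin_width_nm, bin_width_nm)
    counts, edges = np.histogram(d, bins=edges)
    cumulative = np.concatenate([[0.0], np.cumsum(counts)]) / d.size
    mode = edges[int(np.argmax(counts))] + 0.5 * bin_width_nm
    return NTASummary(
        mean_nm=float(d.mean()),
        mode_nm=float(mode),
        bin_edges_nm=edges,
        bin_counts=counts,
        cumulative=cumulative,
        concentration_per_ml=dist.concentration_per_ml * dist.dilution_factor,
    )
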