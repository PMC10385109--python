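"""Ladder-microchannel geometries and per-segment hydraulic resistance.

A ladder network consists of a parent (supply) channel feeding ``N``
bifurcating channels ("rungs") that drain into a collector channel running
alongside the parent.  In the counter-current (anti-parallel) configuration
the collector is drained from the same end the parent is fed, so the flow
directions in the two long channels oppose one another; in the co-current
configuration the collector drains from the far end.

All channel dimensions are stored in micrometres and converted to SI only
when a resistance is computed.  Channels are rectangular ducts of fixed
height (10 um in all tabulated presets); the default resistance model maps
a rectangle onto an equivalent circular capillary through its hydraulic
diameter, and an exact rectangular-duct series solution is available for
sensitivity checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Literal, Mapping

__all__ = [
    "GeometryError",
    "FluidProperties",
    "ChannelSegment",
    "LadderGeometry",
    "hydraulic_diameter",
    "segment_resistance",
    "rectangular_duct_resistance",
    "build_case",
    "load_geometry",
    "list_cases",
]

_UM = 1e-6  # micrometres -> metres

Role = Literal["supply", "collector", "rung", "lead_in", "lead_out"]
Configuration = Literal["counter_current", "co_current"]
ResistanceMode = Literal["hydraulic_diameter", "exact_rectangular"]


class GeometryError(ValueError):
    """Raised for non-physical channel dimensions or unknown presets."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian suspending-fluid properties.

    viscosity
        Dynamic viscosity in Pa*s.  Defaults to 1.0e-3 Pa*s (water-like
        plasma substitute at room temperature).
    """

    viscosity: float = 1.0e-3

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise GeometryError(f"viscosity must be > 0, got {self.viscosity}")


@dataclass(frozen=True)
class ChannelSegment:
    """One straight rectangular channel segment.

    Dimensions in micrometres.  Zero length is permitted only for lead-in /
    lead-out stubs, which are dropped from resistance networks.
    """

    label: str
    width: float
    height: float
    length: float
    role: Role

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise GeometryError(
                f"segment {self.label!r}: width and height must be > 0 "
                f"(got {self.width}, {self.height})"
            )
        if self.length < 0:
            raise GeometryError(f"segment {self.label!r}: length must be >= 0")
        if self.length == 0 and self.role not in ("lead_in", "lead_out"):
            raise GeometryError(
                f"segment {self.label!r}: zero length only allowed for lead segments"
            )


@dataclass(frozen=True)
class LadderGeometry:
    """Parameterised ladder channel.

    parent_width, branch_width
        Widths W_P and W_B of the parent/collector and bifurcating channels (um).
    branch_spacing
        Axial distance L_D between adjacent bifurcating channels (um).
    branch_length
        Length L_B of each bifurcating channel (um).
    height
        Channel height, common to all segments (um).
    n_branches
        Number of bifurcating channels (>= 1; presets use 6).
    configuration
        ``counter_current`` (anti-parallel, default) or ``co_current``.
    lead_in_length, lead_out_length
        Optional straight parent/collector stubs carrying the full flow in
        series with the ladder.  They never change fractional flow ratios.
    """

    parent_width: float
    branch_width: float
    branch_spacing: float
    branch_length: float
    height: float = 10.0
    n_branches: int = 6
    configuration: Configuration = "counter_current"
    case_label: str = "custom"
    lead_in_length: float = 0.0
    lead_out_length: float = 0.0

    def __post_init__(self) -> None:
        for name in ("parent_width", "branch_width", "branch_spacing",
                     "branch_length", "height"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_branches < 1:
            raise GeometryError(f"n_branches must be >= 1, got {self.n_branches}")
        if self.configuration not in ("counter_current", "co_current"):
            raise GeometryError(f"unknown configuration {self.configuration!r}")
        if self.lead_in_length < 0 or self.lead_out_length < 0:
            raise GeometryError("lead lengths must be >= 0")

    # -- derived segments -------------------------------------------------

    def rung_segment(self, i: int) -> ChannelSegment:
        """Bifurcating channel B_i (1-based)."""
        return ChannelSegment(f"B{i}", self.branch_width, self.height,
                              self.branch_length, "rung")

    def supply_segment(self, i: int) -> ChannelSegment:
        """Parent-channel segment between junctions i and i+1 (1-based)."""
        return ChannelSegment(f"P{i}", self.parent_width, self.height,
                              self.branch_spacing, "supply")

    def collector_segment(self, i: int) -> ChannelSegment:
        return ChannelSegment(f"C{i}", self.parent_width, self.height,
                              self.branch_spacing, "collector")

    @property
    def parent_area(self) -> float:
        """Parent cross-sectional area in um^2."""
        return self.parent_width * self.height

    @property
    def branch_area(self) -> float:
        """Bifurcating-channel cross-sectional area in um^2."""
        return self.branch_width * self.height

    def with_configuration(self, configuration: Configuration) -> "LadderGeometry":
        return replace(self, configuration=configuration)


def hydraulic_diameter(width: float, height: float) -> float:
    """Hydraulic diameter D_h = 2wh/(w+h) of a rectangular duct (um in, um out)."""
    if not (width > 0 and height > 0):
        raise GeometryError(
            f"hydraulic_diameter requires positive dimensions, got ({width}, {height})"
        )
    return 2.0 * width * height / (width + height)


def segment_resistance(
    segment: ChannelSegment,
    fluid: FluidProperties | None = None,
    mode: ResistanceMode = "hydraulic_diameter",
) -> float:
    """Hydraulic resistance of a segment in Pa*s/m^3.

    The default mode treats the rectangular duct as a circular capillary of
    radius D_h/2 under Poiseuille's law, R = 8*mu*L / (pi*r^4).  The
    ``exact_rectangular`` mode evaluates the Fourier-series solution for
    laminar flow in a rectangular duct instead.
    """
    fluid = fluid or FluidProperties()
    if segment.length <= 0:
        raise GeometryError(
            f"segment {segment.label!r}: resistance undefined for zero length; "
            "zero-length lead segments must be excluded from networks"
        )
    if mode == "hydraulic_diameter":
        r = 0.5 * hydraulic_diameter(segment.width, segment.height) * _UM
        return 8.0 * fluid.viscosity * (segment.length * _UM) / (math.pi * r**4)
    if mode == "exact_rectangular":
        return rectangular_duct_resistance(
            segment.width, segment.height, segment.length, fluid.viscosity
        )
    raise GeometryError(f"unknown resistance mode {mode!r}")


def rectangular_duct_resistance(
    width: float, height: float, length: float,
    viscosity: float = 1.0e-3, n_terms: int = 51,
) -> float:
    """Exact laminar resistance of a rectangular duct (um dimensions, SI out).

    Series solution with ``a`` the short side and ``b`` the long side:

        R = 12 mu L / (a^3 b S),
        S = 1 - sum_{n odd} (192 a)/(n^5 pi^5 b) tanh(n pi b / 2a)

    The series converges extremely fast; 51 odd terms is far beyond double
    precision already for aspect ratio 1.
    """
    if not (width > 0 and height > 0 and length > 0):
        raise GeometryError("rectangular duct requires positive dimensions")
    a = min(width, height) * _UM
    b = max(width, height) * _UM
    s = 0.0
    for k in range(n_terms):
        n = 2 * k + 1
        s += math.tanh(n * math.pi * b / (2.0 * a)) / n**5
    factor = 1.0 - (192.0 * a) / (math.pi**5 * b) * s
    return 12.0 * viscosity * (length * _UM) / (a**3 * b * factor)


# -- presets ---------------------------------------------------------------

def _load_presets() -> dict[str, dict]:
    text = resources.files("ladderflow.data").joinpath("cases.json").read_text()
    return json.loads(text)


def list_cases() -> list[str]:
    """Identifiers of the packaged geometry presets."""
    return sorted(_load_presets())


def build_case(case_id: str, configuration: Configuration = "counter_current") -> LadderGeometry:
    """Build one of the tabulated six-branch ladder presets (``case1``..``case5``)."""
    presets = _load_presets()
    key = case_id.strip().lower()
    if key not in presets:
        raise GeometryError(
            f"unknown case id {case_id!r}; valid ids: {', '.join(sorted(presets))}"
        )
    p = presets[key]
    return LadderGeometry(
        parent_width=p["WP"], branch_width=p["WB"],
        branch_spacing=p["LD"], branch_length=p["LB"],
        height=p["height"], n_branches=p["n_branches"],
        configuration=configuration, case_label=key,
    )


def load_geometry(spec: Mapping) -> LadderGeometry:
    """Build a geometry from a configuration mapping.

    Accepts either ``{"case": "case1", ...overrides}`` or a full parameter
    set with keys WP, WB, LD, LB and optional height, n_branches,
    configuration, lead_in_length, lead_out_length.
    """
    spec = dict(spec)
    if "parent_width" in spec:  # fully expanded field names (report round-trips)
        return LadderGeometry(**spec)
    if "case" in spec:
        geom = build_case(spec.pop("case"),
                          configuration=spec.pop("configuration", "counter_current"))
        if spec:
            geom = replace(geom, **spec)
        return geom
    try:
        kwargs = dict(
            parent_width=spec.pop("WP"), branch_width=spec.pop("WB"),
            branch_spacing=spec.pop("LD"), branch_length=spec.pop("LB"),
        )
    except KeyError as exc:
        raise GeometryError(f"geometry spec missing key {exc}") from exc
    kwargs.update(spec)
    return LadderGeometry(**kwargs)
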