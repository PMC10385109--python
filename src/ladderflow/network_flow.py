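"""Kirchhoff nodal analysis of the ladder hydraulic-resistance network.

The ladder is mapped onto a resistor network: every channel segment becomes
an edge whose hydraulic resistance plays the role of an electrical
resistance, the volumetric flow the role of the current, and pressure the
role of the voltage.  Flows are obtained by grounding the outlet node and
solving the conductance-Laplacian system ``G p = b`` for the node pressures
with the parent flow injected at the inlet; networks are tiny (a six-branch
ladder has 12 nodes), so a direct dense solve is used throughout.

Node naming: supply junctions ``s1..sN`` along the parent channel,
collector junctions ``c1..cN``.  Branch ``B_i`` is the rung ``s_i - c_i``.
The inlet is always attached at ``s1``; the counter-current (anti-parallel)
outlet drains ``c1`` and the co-current outlet drains ``cN``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .geometry import (
    Configuration,
    FluidProperties,
    GeometryError,
    LadderGeometry,
    ResistanceMode,
    segment_resistance,
)

__all__ = [
    "NetworkError",
    "ResistanceNetwork",
    "FlowSolution",
    "build_ladder_network",
    "assemble_network",
    "solve_flows",
    "fractional_flow_ratios",
]

#: relative tolerance on mass-conservation checks of a returned solution
CONSERVATION_RTOL = 1e-10


class NetworkError(ValueError):
    """Raised for ill-posed resistance networks (disconnected, R <= 0, ...)."""


@dataclass(frozen=True)
class ResistanceNetwork:
    """Resistor-network view of a ladder.

    graph
        Undirected :class:`networkx.Graph`; each edge carries ``resistance``
        (Pa*s/m^3), a ``label`` and a ``kind`` in {rung, supply, collector,
        lead_in, lead_out}.
    inlet, outlet
        Boundary node names.  Flow ``Q_P`` enters at ``inlet`` and leaves at
        ``outlet`` (the pressure reference).
    """

    graph: nx.Graph
    inlet: str
    outlet: str
    n_branches: int

    def validate(self) -> None:
        if self.graph.number_of_nodes() == 0:
            raise NetworkError("empty network")
        if not nx.is_connected(self.graph):
            raise NetworkError("network is disconnected")
        for u, v, data in self.graph.edges(data=True):
            if not data.get("resistance", 0.0) > 0:
                raise NetworkError(f"edge ({u}, {v}) has non-positive resistance")
        for node in (self.inlet, self.outlet):
            if node not in self.graph:
                raise NetworkError(f"boundary node {node!r} missing from network")


@dataclass(frozen=True)
class FlowSolution:
    """Solved flows and pressures for one ladder network.

    segment_flows
        Signed flow (m^3/s) per edge, positive in the stored edge
        orientation (supply/collector edges are stored pointing away from
        the inlet end; rungs point supply -> collector).
    node_pressures
        Pressures in Pa relative to the outlet node.
    branch_flows
        Flow through each rung, ordered ``B_1..B_N`` and oriented
        supply -> collector (always positive for ladder geometries).
    fractional_ratios
        ``Q_i / Q_P`` per branch; sums to 1.
    """

    segment_flows: Mapping[tuple[str, str], float]
    node_pressures: Mapping[str, float]
    branch_flows: np.ndarray
    parent_flow: float
    fractional_ratios: np.ndarray


def build_ladder_network(
    rung_resistances: Sequence[float],
    supply_resistances: Sequence[float],
    collector_resistances: Sequence[float],
    configuration: Configuration = "counter_current",
    lead_in_resistance: float | None = None,
    lead_out_resistance: float | None = None,
) -> ResistanceNetwork:
    """Assemble a ladder resistor network from explicit resistances.

    ``rung_resistances`` has length N; the supply/collector lists have
    length N-1.  This constructor is what geometry-based assembly and the
    randomized solver tests share.
    """
    n = len(rung_resistances)
    if n < 1:
        raise NetworkError("a ladder needs at least one rung")
    if len(supply_resistances) != n - 1 or len(collector_resistances) != n - 1:
        raise NetworkError(
            f"expected {n - 1} supply and collector resistances for {n} rungs"
        )
    g = nx.Graph()
    for i in range(1, n + 1):
        g.add_edge(f"s{i}", f"c{i}", resistance=float(rung_resistances[i - 1]),
                   label=f"B{i}", kind="rung")
    for i in range(1, n):
        g.add_edge(f"s{i}", f"s{i + 1}", resistance=float(supply_resistances[i - 1]),
                   label=f"P{i}", kind="supply")
        g.add_edge(f"c{i}", f"c{i + 1}", resistance=float(collector_resistances[i - 1]),
                   label=f"C{i}", kind="collector")
    inlet, outlet = "s1", ("c1" if configuration == "counter_current" else f"c{n}")
    if lead_in_resistance is not None:
        g.add_edge("inlet", "s1", resistance=float(lead_in_resistance),
                   label="lead_in", kind="lead_in")
        inlet = "inlet"
    if lead_out_resistance is not None:
        g.add_edge(outlet, "outlet", resistance=float(lead_out_resistance),
                   label="lead_out", kind="lead_out")
        outlet = "outlet"
    net = ResistanceNetwork(graph=g, inlet=inlet, outlet=outlet, n_branches=n)
    net.validate()
    return net


def assemble_network(
    geometry: LadderGeometry,
    fluid: FluidProperties | None = None,
    resistance_mode: ResistanceMode = "hydraulic_diameter",
) -> ResistanceNetwork:
    """Build the resistor network of a ladder geometry.

    Produces N rung edges (width W_B, length L_B) and N-1 supply plus N-1
    collector edges (width W_P, length L_D).  Zero-length lead segments are
    omitted; nonzero lead lengths add series edges that carry the full
    parent flow and therefore never change the fractional ratios.
    """
    fluid = fluid or FluidProperties()
    n = geometry.n_branches
    rungs = [segment_resistance(geometry.rung_segment(i), fluid, resistance_mode)
             for i in range(1, n + 1)]
    supply = [segment_resistance(geometry.supply_segment(i), fluid, resistance_mode)
              for i in range(1, n)]
    collector = [segment_resistance(geometry.collector_segment(i), fluid, resistance_mode)
                 for i in range(1, n)]

    def _lead(length: float, label: str) -> float | None:
        if length <= 0:
            return None
        from .geometry import ChannelSegment
        seg = ChannelSegment(label, geometry.parent_width, geometry.height,
                             length, "lead_in" if label == "lead_in" else "lead_out")
        return segment_resistance(seg, fluid, resistance_mode)

    return build_ladder_network(
        rungs, supply, collector, geometry.configuration,
        lead_in_resistance=_lead(geometry.lead_in_length, "lead_in"),
        lead_out_resistance=_lead(geometry.lead_out_length, "lead_out"),
    )


def solve_flows(network: ResistanceNetwork, parent_flow: float = 1.0) -> FlowSolution:
    """Solve Kirchhoff's laws on the network for a given parent flow.

    Nodal analysis: with edge conductances ``1/R`` the node pressures solve
    the graph Laplacian system with ``+Q_P`` injected at the inlet and the
    outlet grounded.  Fractional ratios are independent of both ``Q_P`` and
    the fluid viscosity, which scale out of the linear system.
    """
    network.validate()
    if not parent_flow > 0:
        raise NetworkError(f"parent flow must be > 0, got {parent_flow}")
    g = network.graph
    nodes = list(g.nodes)
    index = {node: k for k, node in enumerate(nodes)}
    n = len(nodes)
    lap = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        cond = 1.0 / data["resistance"]
        iu, iv = index[u], index[v]
        lap[iu, iu] += cond
        lap[iv, iv] += cond
        lap[iu, iv] -= cond
        lap[iv, iu] -= cond
    rhs = np.zeros(n)
    rhs[index[network.inlet]] = parent_flow
    rhs[index[network.outlet]] = -parent_flow
    keep = [k for k in range(n) if k != index[network.outlet]]
    pressures = np.zeros(n)
    try:
        pressures[keep] = np.linalg.solve(lap[np.ix_(keep, keep)], rhs[keep])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validate()
        raise NetworkError("singular nodal system") from exc

    node_pressures = {node: float(pressures[index[node]]) for node in nodes}
    segment_flows: dict[tuple[str, str], float] = {}
    for u, v, data in g.edges(data=True):
        segment_flows[(u, v)] = (pressures[index[u]] - pressures[index[v]]) / data["resistance"]

    # rung flows oriented supply -> collector; positive throughout for
    # geometry-derived ladders, signed in arbitrary heterogeneous networks
    branch_flows = np.empty(network.n_branches)
    for i in range(1, network.n_branches + 1):
        u, v = f"s{i}", f"c{i}"
        q = segment_flows.get((u, v))
        if q is None:
            q = -segment_flows[(v, u)]
        branch_flows[i - 1] = q

    # interior-node conservation check
    boundary = {network.inlet, network.outlet}
    for node in nodes:
        if node in boundary:
            continue
        net_flow = sum(
            segment_flows[(u, v)] * (1 if u == node else -1)
            for (u, v) in segment_flows
            if node in (u, v)
        )
        if abs(net_flow) > CONSERVATION_RTOL * parent_flow:
            raise NetworkError(f"flow conservation violated at node {node!r}")
    total = branch_flows.sum()
    if abs(total - parent_flow) > CONSERVATION_RTOL * parent_flow:
        raise NetworkError("branch flows do not sum to the parent flow")

    return FlowSolution(
        segment_flows=segment_flows,
        node_pressures=node_pressures,
        branch_flows=branch_flows,
        parent_flow=float(parent_flow),
        fractional_ratios=branch_flows / parent_flow,
    )


def fractional_flow_ratios(solution: FlowSolution) -> np.ndarray:
    """Per-branch fractional flow ratios ``Q_i/Q_P`` (non-negative, sum 1)."""
    return np.asarray(solution.fractional_ratios, dtype=float)
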