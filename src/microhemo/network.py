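"""Poiseuille hydraulic model of the embryonic zebrafish trunk vasculature.

The trunk is represented as a ladder network: the dorsal aorta (DA) and
posterior cardinal vein (PCV) are the lower rails, the dorsal longitudinal
anastomotic vessel (DLAV) the upper rail, arterial/venous segmental vessels
(SeA/SeV) the rungs, and a distal DA-PCV anastomosis (ECL) closes the loop.
Each vessel contributes a Poiseuille resistance plus a per-cell occlusive
increment; red cells are advected as points and routed stochastically at
bifurcations with a flux-biased (plasma-skimming) rule.

Units: geometry in micrometres, pressures in Pa, fluxes in m^3/s,
velocities in m/s internally (cm/s in reported tables), resistances in
Pa.s/m^3.
"""

from __future__ import annotations

import copy
import json
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

UM = 1e-6                 # metres per micrometre
DYN_CM2_PER_PA = 10.0
CMS_PER_MS = 100.0

VESSEL_KINDS = ("DA", "SeA", "SeV", "DLAV", "PCV", "ECL")

__all__ = [
    "FluidParams", "VesselEdge", "BoundaryConditions", "TrunkNetwork",
    "NetworkState", "RBCState", "TransportResult", "AdaptationResult",
    "build_trunk_network", "edge_resistance", "solve_flow", "partition_rbc",
    "simulate_rbc_transport", "expected_cell_flux", "amputate", "adapt_radii",
    "network_to_json", "network_from_json",
    "InvalidParameterError", "TopologyError", "UndefinedPartitionError",
]


class InvalidParameterError(ValueError):
    """A geometric or physical parameter violates its invariant."""


class TopologyError(RuntimeError):
    """The network graph cannot support the requested operation."""


class UndefinedPartitionError(ValueError):
    """Cell partitioning is undefined (e.g. all candidate fluxes are zero)."""


@dataclass(frozen=True)
class FluidParams:
    """Newtonian plasma; dynamic viscosity in Pa.s."""

    mu: float = 1.0e-3

    def __post_init__(self):
        if not self.mu > 0:
            raise InvalidParameterError(f"viscosity must be positive, got {self.mu}")


@dataclass
class VesselEdge:
    id: str
    head_node: str
    tail_node: str
    length_um: float
    radius_um: float
    alpha_c: float = 0.0          # occlusive strength, Pa.s/m^3 per cell
    kind: str = "SeA"

    def __post_init__(self):
        if not self.length_um > 0:
            raise InvalidParameterError(f"edge {self.id}: length must be > 0")
        if not self.radius_um > 0:
            raise InvalidParameterError(f"edge {self.id}: radius must be > 0")
        if self.alpha_c < 0:
            raise InvalidParameterError(f"edge {self.id}: alpha_c must be >= 0")
        if self.head_node == self.tail_node:
            raise InvalidParameterError(f"edge {self.id}: head and tail coincide")
        if self.kind not in VESSEL_KINDS:
            raise InvalidParameterError(
                f"edge {self.id}: unknown kind {self.kind!r}; expected one of {VESSEL_KINDS}")


@dataclass
class BoundaryConditions:
    inlet_node: str
    outlet_node: str
    inlet_pressure_pa: float
    outlet_pressure_pa: float

    def __post_init__(self):
        if not self.inlet_pressure_pa > self.outlet_pressure_pa:
            raise InvalidParameterError("inlet pressure must exceed outlet pressure")


@dataclass
class TrunkNetwork:
    """Vessel graph with node positions (um) and pressure boundary conditions."""

    nodes: dict          # node id -> (x_um, y_um)
    edges: list          # list[VesselEdge]
    boundary: BoundaryConditions

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = set()
        for e in self.edges:
            if e.id in ids:
                raise InvalidParameterError(f"duplicate edge id {e.id}")
            ids.add(e.id)
            for n in (e.head_node, e.tail_node):
                if n not in self.nodes:
                    raise TopologyError(f"edge {e.id} references unknown node {n}")
        for n in (self.boundary.inlet_node, self.boundary.outlet_node):
            if n not in self.nodes:
                raise TopologyError(f"boundary node {n} not in network")

    @property
    def edge_map(self) -> dict:
        return {e.id: e for e in self.edges}

    def edges_of_kind(self, kind: str) -> list:
        return [e for e in self.edges if e.kind == kind]

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.head_node, e.tail_node, key=e.id)
        return g

    def is_connected_inlet_outlet(self) -> bool:
        g = self.graph()
        return nx.has_path(g, self.boundary.inlet_node, self.boundary.outlet_node)

    def copy(self) -> "TrunkNetwork":
        return copy.deepcopy(self)


@dataclass
class NetworkState:
    """Solved pressures and fluxes. Fluxes are signed, positive head->tail."""

    node_pressures_pa: dict
    edge_fluxes_m3s: dict
    edge_velocities_ms: dict
    max_relative_residual: float

    def velocity_cms(self, edge_id: str) -> float:
        return self.edge_velocities_ms[edge_id] * CMS_PER_MS


@dataclass
class RBCState:
    """Discrete red cells located by (edge id, arclength um)."""

    cells: list = field(default_factory=list)

    @classmethod
    def empty(cls) -> "RBCState":
        return cls(cells=[])

    @property
    def counts(self) -> dict:
        tally: dict = {}
        for edge_id, _s in self.cells:
            tally[edge_id] = tally.get(edge_id, 0) + 1
        return tally


def edge_resistance(edge: VesselEdge, fluid: FluidParams, n_cells: int = 0) -> float:
    """Hydraulic resistance 8*mu*L/(pi*r^4) plus n_cells occlusive increments."""
    if n_cells < 0:
        raise InvalidParameterError("n_cells must be >= 0")
    length_m = edge.length_um * UM
    radius_m = edge.radius_um * UM
    poiseuille = 8.0 * fluid.mu * length_m / (math.pi * radius_m ** 4)
    return poiseuille + n_cells * edge.alpha_c


def build_trunk_network(
    n_se_pairs: int = 16,
    da_length: float = 75.0,
    se_length: float = 100.0,
    se_radius: float = 3.0,
    trunk_radius: float = 10.0,
    alpha_c_profile: tuple = (5.0e15, 1.0e15),
    *,
    dlav_radius: float | None = None,
    ecl_length: float = 150.0,
    inlet_pressure_pa: float = 150.0,
    outlet_pressure_pa: float = 0.0,
) -> TrunkNetwork:
    """Default trunk ladder topology.

    ``da_length`` is the axial spacing between consecutive rung pairs. SeA
    rungs rise from DA nodes to the DLAV, SeV rungs (offset by half a
    spacing) drain the DLAV into the PCV, and a single ECL edge joins the
    distal DA to the distal PCV. ``alpha_c_profile`` gives the occlusive
    strength at the head (proximal) and tail (distal) of the trunk; every
    edge takes the linear interpolant at its axial midpoint.
    """
    if n_se_pairs < 2:
        raise InvalidParameterError("n_se_pairs must be >= 2")
    for name, v in (("da_length", da_length), ("se_length", se_length),
                    ("se_radius", se_radius), ("trunk_radius", trunk_radius),
                    ("ecl_length", ecl_length)):
        if not v > 0:
            raise InvalidParameterError(f"{name} must be positive, got {v}")
    a_head, a_tail = alpha_c_profile
    if a_head < 0 or a_tail < 0:
        raise InvalidParameterError("alpha_c values must be >= 0")
    if dlav_radius is None:
        dlav_radius = 1.5 * se_radius

    n = n_se_pairs
    dx = da_length
    y_dlav = se_length
    y_pcv = -0.3 * se_length
    x_max = n * dx + 0.5 * dx

    def alpha_at(x_mid: float) -> float:
        return a_head + (a_tail - a_head) * (x_mid / x_max)

    nodes: dict = {}
    for i in range(n + 1):
        nodes[f"da_{i}"] = (i * dx, 0.0)
    for i in range(1, n + 1):
        nodes[f"la_{i}"] = (i * dx, y_dlav)           # DLAV node at SeA foot
        nodes[f"lv_{i}"] = (i * dx + 0.5 * dx, y_dlav)  # DLAV node at SeV foot
        nodes[f"pv_{i}"] = (i * dx + 0.5 * dx, y_pcv)
    nodes["pcv_0"] = (0.0, y_pcv)

    edges: list = []

    def add(eid, head, tail, length, radius, kind):
        x_mid = 0.5 * (nodes[head][0] + nodes[tail][0])
        edges.append(VesselEdge(eid, head, tail, length, radius,
                                alpha_c=alpha_at(x_mid), kind=kind))

    for i in range(n):
        add(f"DA_{i + 1}", f"da_{i}", f"da_{i + 1}", dx, trunk_radius, "DA")
    for i in range(1, n + 1):
        add(f"SeA_{i}", f"da_{i}", f"la_{i}", se_length, se_radius, "SeA")
        add(f"SeV_{i}", f"lv_{i}", f"pv_{i}", se_length + abs(y_pcv), se_radius, "SeV")
    # DLAV rail alternates la_1, lv_1, la_2, lv_2, ...
    rail = []
    for i in range(1, n + 1):
        rail.extend([f"la_{i}", f"lv_{i}"])
    for k in range(len(rail) - 1):
        add(f"DLAV_{k + 1}", rail[k], rail[k + 1], 0.5 * dx, dlav_radius, "DLAV")
    # PCV rail from the outlet towards the tail
    pcv_nodes = ["pcv_0"] + [f"pv_{i}" for i in range(1, n + 1)]
    for k in range(len(pcv_nodes) - 1):
        length = abs(nodes[pcv_nodes[k + 1]][0] - nodes[pcv_nodes[k]][0])
        add(f"PCV_{k + 1}", pcv_nodes[k + 1], pcv_nodes[k], length, trunk_radius, "PCV")
    add("ECL", f"da_{n}", f"pv_{n}", ecl_length, trunk_radius, "ECL")

    boundary = BoundaryConditions("da_0", "pcv_0", inlet_pressure_pa, outlet_pressure_pa)
    return TrunkNetwork(nodes=nodes, edges=edges, boundary=boundary)


def solve_flow(network: TrunkNetwork, fluid: FluidParams,
               rbc: RBCState | None = None) -> NetworkState:
    """Solve nodal pressure balance with Dirichlet inlet/outlet pressures.

    Edge resistances include the occlusive increment for the cells currently
    on each edge. Raises :class:`TopologyError` if the graph cannot connect
    every node to the boundary (singular system).
    """
    counts = rbc.counts if rbc is not None else {}
    bc = network.boundary
    g = network.graph()
    comp_inlet = nx.node_connected_component(g, bc.inlet_node)
    if bc.outlet_node not in comp_inlet:
        raise TopologyError("inlet and outlet are not connected")
    stray = [n for n in network.nodes if n not in comp_inlet
             and n not in nx.node_connected_component(g, bc.outlet_node)]
    if stray:
        raise TopologyError(f"nodes not connected to boundary: {sorted(stray)}")

    node_ids = sorted(network.nodes)
    idx = {n: i for i, n in enumerate(node_ids)}
    n_nodes = len(node_ids)
    conduct = {}
    for e in network.edges:
        conduct[e.id] = 1.0 / edge_resistance(e, fluid, counts.get(e.id, 0))

    A = np.zeros((n_nodes, n_nodes))
    b = np.zeros(n_nodes)
    for e in network.edges:
        gi, gj = idx[e.head_node], idx[e.tail_node]
        c = conduct[e.id]
        A[gi, gi] += c
        A[gj, gj] += c
        A[gi, gj] -= c
        A[gj, gi] -= c
    for node, p in ((bc.inlet_node, bc.inlet_pressure_pa),
                    (bc.outlet_node, bc.outlet_pressure_pa)):
        i = idx[node]
        A[i, :] = 0.0
        A[i, i] = 1.0
        b[i] = p
    try:
        p = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise TopologyError("singular hydraulic system") from exc

    pressures = {n: float(p[idx[n]]) for n in node_ids}
    fluxes = {}
    velocities = {}
    for e in network.edges:
        q = conduct[e.id] * (pressures[e.head_node] - pressures[e.tail_node])
        fluxes[e.id] = q
        velocities[e.id] = q / (math.pi * (e.radius_um * UM) ** 2)

    # conservation residual at interior nodes, relative to the inlet flux
    net = {n: 0.0 for n in node_ids}
    for e in network.edges:
        net[e.head_node] -= fluxes[e.id]
        net[e.tail_node] += fluxes[e.id]
    inlet_flux = abs(net[bc.inlet_node])
    interior = [n for n in node_ids if n not in (bc.inlet_node, bc.outlet_node)]
    resid = max((abs(net[n]) for n in interior), default=0.0)
    rel = resid / inlet_flux if inlet_flux > 0 else resid
    return NetworkState(pressures, fluxes, velocities, rel)


def partition_rbc(branch_fluxes, branch_radii=None, bias_exponent: float = 2.0):
    """Branch selection probabilities for a cell arriving at a bifurcation.

    Probability of branch i is proportional to flux_i**bias_exponent
    (plasma-skimming surrogate: exponents > 1 over-favour the high-flow
    branch). ``branch_radii`` is accepted for interface symmetry but the
    rule is purely flux-based.
    """
    q = np.asarray(branch_fluxes, dtype=float)
    if np.any(q < 0):
        raise InvalidParameterError("branch fluxes must be >= 0")
    if bias_exponent < 1:
        raise InvalidParameterError("bias_exponent must be >= 1")
    total = q.sum()
    if total == 0:
        raise UndefinedPartitionError("all branch fluxes are zero")
    w = q ** bias_exponent
    return w / w.sum()


@dataclass
class TransportResult:
    trajectories: pd.DataFrame       # time_s, cell_id, edge_id, arclength_um
    edge_series: pd.DataFrame        # time_s, edge_id, n_cells, flux_m3s, velocity_cms
    edge_traversals: dict            # edge_id -> number of cells that entered it
    n_injected: int
    n_exited: int
    n_stranded: int
    seed: int


def _outgoing(network: TrunkNetwork, state: NetworkState, node: str, tol: float):
    """Edges carrying flow out of ``node``: list of (edge, outflux, entry_s, direction)."""
    out = []
    for e in network.edges:
        q = state.edge_fluxes_m3s[e.id]
        if e.head_node == node and q > tol:
            out.append((e, q, 0.0, +1))
        elif e.tail_node == node and q < -tol:
            out.append((e, -q, e.length_um, -1))
    return out


def simulate_rbc_transport(
    network: TrunkNetwork,
    fluid: FluidParams,
    inflow_rate: float,
    duration: float,
    dt: float = 0.05,
    bias_exponent: float = 2.0,
    seed: int = 0,
    occlusion_feedback: bool = False,
) -> TransportResult:
    """Advect point cells through the solved flow field.

    Cells are injected at the inlet at regular intervals 1/inflow_rate and
    advect at the local edge mean velocity; at each junction a downstream
    branch is drawn from :func:`partition_rbc`. Sub-stepping guarantees a
    cell crosses at most one node per sub-step. With ``occlusion_feedback``
    the pressure field is re-solved every recording step using the current
    per-edge cell counts.
    """
    if inflow_rate <= 0 or duration <= 0 or dt <= 0:
        raise InvalidParameterError("inflow_rate, duration and dt must be positive")
    rng = np.random.default_rng(seed)
    state = solve_flow(network, fluid, RBCState.empty())
    flux_tol = 1e-12 * max(abs(q) for q in state.edge_fluxes_m3s.values())
    bc = network.boundary

    n_steps = int(round(duration / dt))
    arrivals = np.arange(1, int(math.floor(duration * inflow_rate)) + 1) / inflow_rate
    next_arrival = 0

    # cell_id -> [edge, s_um, direction]
    alive: dict = {}
    traversals: dict = {e.id: 0 for e in network.edges}
    n_exited = 0
    n_stranded = 0
    traj_rows = []
    series_rows = []

    def speed_ums(edge) -> float:
        return abs(state.edge_velocities_ms[edge.id]) / UM  # um/s

    def route_from(node: str):
        """Pick an outgoing edge at ``node``; None means the cell leaves."""
        nonlocal n_stranded
        if node == bc.outlet_node:
            return None
        out = _outgoing(network, state, node, flux_tol)
        if not out:
            warnings.warn(f"cell stranded at node {node}: no downstream flux; removed",
                          RuntimeWarning, stacklevel=2)
            n_stranded += 1
            return None
        probs = partition_rbc([q for _, q, _, _ in out],
                              bias_exponent=bias_exponent)
        k = int(rng.choice(len(out), p=probs))
        return out[k]

    cell_counter = 0
    for step in range(n_steps):
        t0 = step * dt
        if occlusion_feedback and alive:
            state = solve_flow(network, fluid,
                               RBCState([(edge.id, s) for edge, s, _d in alive.values()]))
        # adaptive sub-stepping: no cell may finish an edge within one sub-step
        transit = [e.length_um / speed_ums(e) for e in network.edges
                   if speed_ums(e) > 0]
        min_transit = min(transit) if transit else dt
        n_sub = max(1, int(math.ceil(dt / min_transit)) + 1)
        sub_dt = dt / n_sub

        for j in range(n_sub):
            t_sub = t0 + j * sub_dt
            # injections due by now
            while next_arrival < len(arrivals) and arrivals[next_arrival] <= t_sub + sub_dt:
                choice = route_from(bc.inlet_node)
                cell_id = cell_counter
                cell_counter += 1
                if choice is not None:
                    edge, _q, entry_s, direction = choice
                    alive[cell_id] = [edge, entry_s, direction]
                    traversals[edge.id] += 1
                else:
                    n_exited += 1
                next_arrival += 1
            # advect
            for cell_id in sorted(alive):
                edge, s, direction = alive[cell_id]
                v = speed_ums(edge)
                s_new = s + direction * v * sub_dt
                if 0.0 <= s_new <= edge.length_um:
                    alive[cell_id][1] = s_new
                    continue
                # reached a node: spend the leftover time on the next edge
                end_s = edge.length_um if direction > 0 else 0.0
                t_left = sub_dt - (abs(end_s - s) / v if v > 0 else 0.0)
                node = edge.tail_node if direction > 0 else edge.head_node
                choice = route_from(node)
                if choice is None:
                    del alive[cell_id]
                    n_exited += 1
                    continue
                nedge, _q, entry_s, ndir = choice
                traversals[nedge.id] += 1
                nv = speed_ums(nedge)
                alive[cell_id] = [nedge, entry_s + ndir * nv * max(t_left, 0.0), ndir]

        t1 = (step + 1) * dt
        counts: dict = {}
        for edge, s, _d in alive.values():
            counts[edge.id] = counts.get(edge.id, 0) + 1
        for e in network.edges:
            series_rows.append((t1, e.id, counts.get(e.id, 0),
                                state.edge_fluxes_m3s[e.id],
                                state.edge_velocities_ms[e.id] * CMS_PER_MS))
        for cell_id in sorted(alive):
            edge, s, _d = alive[cell_id]
            traj_rows.append((t1, cell_id, edge.id, s))

    trajectories = pd.DataFrame(traj_rows,
                                columns=["time_s", "cell_id", "edge_id", "arclength_um"])
    edge_series = pd.DataFrame(series_rows,
                               columns=["time_s", "edge_id", "n_cells",
                                        "flux_m3s", "velocity_cms"])
    return TransportResult(trajectories, edge_series, traversals,
                           cell_counter, n_exited, n_stranded, seed)


def expected_cell_flux(network: TrunkNetwork, state: NetworkState,
                       bias_exponent: float = 2.0,
                       inflow_rate: float = 1.0) -> dict:
    """Deterministic expected cell flux (cells/s) per edge.

    With occlusion feedback off the routing probabilities are fixed, so the
    expected cell throughput obeys a linear balance; pressures decrease
    strictly along the flow so nodes can be processed in descending pressure
    order.
    """
    flux_tol = 1e-12 * max(abs(q) for q in state.edge_fluxes_m3s.values())
    inflow: dict = {n: 0.0 for n in network.nodes}
    inflow[network.boundary.inlet_node] = inflow_rate
    cell_flux: dict = {e.id: 0.0 for e in network.edges}
    order = sorted(network.nodes, key=lambda n: -state.node_pressures_pa[n])
    for node in order:
        if node == network.boundary.outlet_node:
            continue
        total_in = inflow[node]
        if total_in == 0:
            continue
        out = _outgoing(network, state, node, flux_tol)
        if not out:
            continue
        probs = partition_rbc([q for _, q, _, _ in out], bias_exponent=bias_exponent)
        for (edge, _q, _s, direction), p in zip(out, probs):
            f = total_in * p
            cell_flux[edge.id] += f
            downstream = edge.tail_node if direction > 0 else edge.head_node
            inflow[downstream] += f
    return cell_flux


def amputate(network: TrunkNetwork, n_distal_rungs: int = 0) -> TrunkNetwork:
    """Sever the distal loop: drop the ECL, the ``n_distal_rungs`` most
    distal SeA/SeV pairs, and any rail stubs left dangling.

    Stubs are pruned by repeatedly deleting non-boundary nodes of degree
    <= 1. Raises :class:`TopologyError` if the cut disconnects the inlet
    from the outlet.
    """
    sea = sorted(network.edges_of_kind("SeA"),
                 key=lambda e: network.nodes[e.head_node][0])
    sev = sorted(network.edges_of_kind("SeV"),
                 key=lambda e: network.nodes[e.head_node][0])
    if n_distal_rungs < 0 or n_distal_rungs >= len(sea):
        raise InvalidParameterError(
            f"n_distal_rungs must be in [0, {len(sea) - 1}], got {n_distal_rungs}")
    drop = {e.id for e in network.edges_of_kind("ECL")}
    if n_distal_rungs:
        drop |= {e.id for e in sea[-n_distal_rungs:]}
        drop |= {e.id for e in sev[-n_distal_rungs:]}

    edges = [copy.deepcopy(e) for e in network.edges if e.id not in drop]
    bc = network.boundary
    protected = {bc.inlet_node, bc.outlet_node}
    while True:
        degree: dict = {}
        for e in edges:
            degree[e.head_node] = degree.get(e.head_node, 0) + 1
            degree[e.tail_node] = degree.get(e.tail_node, 0) + 1
        dangling = {n for n, d in degree.items() if d <= 1 and n not in protected}
        if not dangling:
            break
        edges = [e for e in edges if e.head_node not in dangling
                 and e.tail_node not in dangling]
    used = {n for e in edges for n in (e.head_node, e.tail_node)} | protected
    nodes = {n: xy for n, xy in network.nodes.items() if n in used}
    cut = TrunkNetwork(nodes=nodes, edges=edges,
                       boundary=copy.deepcopy(network.boundary))
    if not cut.is_connected_inlet_outlet():
        raise TopologyError("amputation disconnected the inlet from the outlet")
    return cut


@dataclass
class AdaptationResult:
    radius_trajectory_um: dict       # edge_id -> np.ndarray over iterations
    sigma_trajectory_dyncm2: dict    # edge_id -> np.ndarray
    converged: bool
    n_iter: int
    network: TrunkNetwork            # network with final radii


def adapt_radii(
    network: TrunkNetwork,
    fluid: FluidParams,
    rbc: RBCState | None,
    set_point_dyncm2: float,
    gain: float = 0.25,
    max_iter: int = 500,
    tol: float = 1e-6,
    edges: list | None = None,
    resolve: bool = True,
) -> AdaptationResult:
    """Wall-shear set-point remodeling: r <- r * (1 + gain*(sigma/sigma_set - 1)).

    ``edges`` selects which vessels adapt (default: all SeA edges, or all
    edges if the network has none). With ``resolve`` the flow is re-solved
    after every radius update; without it the initial fluxes are held fixed
    (single-vessel closed-form regime). Non-convergence at ``max_iter`` is
    flagged on the result, not raised.
    """
    from . import wss as wss_mod

    if not set_point_dyncm2 > 0:
        raise InvalidParameterError("set point must be positive")
    if not 0 < gain <= 1:
        raise InvalidParameterError("gain must lie in (0, 1]")
    net = network.copy()
    emap = net.edge_map
    if edges is None:
        edges = [e.id for e in net.edges_of_kind("SeA")] or [e.id for e in net.edges]
    for eid in edges:
        if eid not in emap:
            raise InvalidParameterError(f"unknown edge id {eid}")

    state = solve_flow(net, fluid, rbc)
    fixed_flux = {eid: state.edge_fluxes_m3s[eid] for eid in edges}

    r_traj = {eid: [emap[eid].radius_um] for eid in edges}
    s_traj: dict = {eid: [] for eid in edges}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if resolve:
            state = solve_flow(net, fluid, rbc)
        sigmas = {}
        for eid in edges:
            e = emap[eid]
            if resolve:
                q = state.edge_fluxes_m3s[eid]
            else:
                q = fixed_flux[eid]
            v_ms = abs(q) / (math.pi * (e.radius_um * UM) ** 2)
            params = wss_mod.WSSParams(mu=fluid.mu, radius_um=e.radius_um)
            sigmas[eid] = wss_mod.plasma_wss(params, v_ms * CMS_PER_MS)
        for eid in edges:
            s_traj[eid].append(sigmas[eid])
        if all(abs(sigmas[eid] - set_point_dyncm2) / set_point_dyncm2 < tol
               for eid in edges):
            converged = True
            break
        for eid in edges:
            e = emap[eid]
            e.radius_um *= 1.0 + gain * (sigmas[eid] / set_point_dyncm2 - 1.0)
            r_traj[eid].append(e.radius_um)

    return AdaptationResult(
        {eid: np.array(v) for eid, v in r_traj.items()},
        {eid: np.array(v) for eid, v in s_traj.items()},
        converged, it, net)


NETWORK_SCHEMA = "trunk-network/1"


def network_to_json(network: TrunkNetwork) -> str:
    doc = {
        "schema": NETWORK_SCHEMA,
        "nodes": [{"id": n, "x_um": xy[0], "y_um": xy[1]}
                  for n, xy in sorted(network.nodes.items())],
        "edges": [{"id": e.id, "head": e.head_node, "tail": e.tail_node,
                   "length_um": e.length_um, "radius_um": e.radius_um,
                   "alpha_c": e.alpha_c, "kind": e.kind}
                  for e in network.edges],
        "boundary": {
            "inlet_node": network.boundary.inlet_node,
            "outlet_node": network.boundary.outlet_node,
            "inlet_pressure_pa": network.boundary.inlet_pressure_pa,
            "outlet_pressure_pa": network.boundary.outlet_pressure_pa,
        },
    }
    return json.dumps(doc, indent=2)


def network_from_json(text: str) -> TrunkNetwork:
    doc = json.loads(text)
    if doc.get("schema") != NETWORK_SCHEMA:
        raise InvalidParameterError(
            f"unsupported network schema: {doc.get('schema')!r}")
    nodes = {n["id"]: (float(n["x_um"]), float(n["y_um"])) for n in doc["nodes"]}
    edges = [VesselEdge(e["id"], e["head"], e["tail"], float(e["length_um"]),
                        float(e["radius_um"]), float(e.get("alpha_c", 0.0)),
                        e.get("kind", "SeA"))
             for e in doc["edges"]]
    b = doc["boundary"]
    boundary = BoundaryConditions(b["inlet_node"], b["outlet_node"],
                                  float(b["inlet_pressure_pa"]),
                                  float(b["outlet_pressure_pa"]))
    return TrunkNetwork(nodes=nodes, edges=edges, boundary=boundary)
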