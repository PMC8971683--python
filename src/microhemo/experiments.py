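"""End-to-end amputation experiment on the model trunk network.

Solves the intact network, measures per-SeA hemodynamics (cell flux,
number density, plasma WSS, peak shear stress portion), severs the distal
loop, re-runs everything, and tabulates fold changes ordered by distance
from the cut. Cell flux and density come from the deterministic expected
routing balance; the peak-portion statistic uses the stochastic transport
simulation's per-frame occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as net_mod
from . import wss as wss_mod


@dataclass(frozen=True)
class AmputationConfig:
    n_se_pairs: int = 16
    n_distal_rungs: int = 0
    da_length_um: float = 75.0
    se_length_um: float = 100.0
    se_radius_um: float = 3.0
    trunk_radius_um: float = 10.0
    alpha_c_head: float = 5.0e15
    alpha_c_tail: float = 1.0e15
    mu_pas: float = 1.0e-3
    cell_length_um: float = 6.0
    inflow_rate_cells_s: float = 30.0
    duration_s: float = 40.0
    dt_s: float = 0.05
    bias_exponent: float = 2.0
    occlusion_feedback: bool = False


@dataclass
class VesselSummary:
    """Per-SeA metrics for one (intact or amputated) run."""

    table: pd.DataFrame          # edge_id, x_um, cell_flux_per_s, density_cm,
                                 # velocity_cms, sigma_p_dyncm2, peak_portion
    plasma_pool: np.ndarray      # pooled per-frame plasma WSS, all Se vessels
    state: net_mod.NetworkState
    transport: net_mod.TransportResult
    decompositions: dict         # edge_id -> WSSDecomposition

    def apply_threshold(self, threshold_dyncm2: float) -> None:
        portions = [wss_mod.peak_stress_portion(self.decompositions[eid],
                                                threshold_dyncm2)
                    for eid in self.table["edge_id"]]
        self.table["peak_portion"] = portions


@dataclass
class AmputationComparison:
    config: AmputationConfig
    seed: int
    threshold_dyncm2: float      # activation threshold from the intact run
    pre: VesselSummary
    post: VesselSummary
    table: pd.DataFrame = field(init=False)

    def __post_init__(self):
        merged = self.post.table.merge(
            self.pre.table, on=["edge_id"], suffixes=("_post", "_pre"))
        for col in ("cell_flux_per_s", "density_cm", "sigma_p_dyncm2",
                    "peak_portion"):
            pre = merged[f"{col}_pre"]
            merged[f"{col}_fold"] = np.where(pre > 0,
                                             merged[f"{col}_post"] / pre, np.inf)
        merged = merged.sort_values("x_um_post", ascending=False).reset_index(drop=True)
        merged.insert(1, "rank_from_cut", np.arange(1, len(merged) + 1))
        self.table = merged


def _se_metrics(network: net_mod.TrunkNetwork, fluid: net_mod.FluidParams,
                config: AmputationConfig, seed: int) -> VesselSummary:
    state = net_mod.solve_flow(network, fluid, net_mod.RBCState.empty())
    cell_flux = net_mod.expected_cell_flux(network, state,
                                           bias_exponent=config.bias_exponent,
                                           inflow_rate=config.inflow_rate_cells_s)
    transport = net_mod.simulate_rbc_transport(
        network, fluid, config.inflow_rate_cells_s, config.duration_s,
        dt=config.dt_s, bias_exponent=config.bias_exponent, seed=seed,
        occlusion_feedback=config.occlusion_feedback)
    series = transport.edge_series

    se_edges = network.edges_of_kind("SeA")
    isv_edges = se_edges + network.edges_of_kind("SeV")

    pool = []
    sigma_p_by_edge = {}
    for e in isv_edges:
        v_cms = abs(state.velocity_cms(e.id))
        params = wss_mod.WSSParams(mu=fluid.mu, radius_um=e.radius_um,
                                   cell_length_um=config.cell_length_um,
                                   alpha_c=e.alpha_c)
        sigma_p_by_edge[e.id] = wss_mod.plasma_wss(params, v_cms)
        n_frames = (series["edge_id"] == e.id).sum()
        pool.append(np.full(n_frames, sigma_p_by_edge[e.id]))
    pool = np.concatenate(pool) if pool else np.array([])

    rows = []
    decomps = {}
    for e in se_edges:
        v_cms = abs(state.velocity_cms(e.id))
        params = wss_mod.WSSParams(mu=fluid.mu, radius_um=e.radius_um,
                                   cell_length_um=config.cell_length_um,
                                   alpha_c=e.alpha_c)
        counts = series.loc[series["edge_id"] == e.id, "n_cells"].to_numpy()
        decomps[e.id] = wss_mod.build_wss_decomposition(
            [int(c) for c in counts], e.length_um, v_cms, params, vessel_id=e.id)
        density = cell_flux[e.id] / v_cms if v_cms > 0 else 0.0   # cells per cm
        x_mid = 0.5 * (network.nodes[e.head_node][0] + network.nodes[e.tail_node][0])
        rows.append((e.id, x_mid, cell_flux[e.id], density, v_cms,
                     sigma_p_by_edge[e.id], np.nan))
    table = pd.DataFrame(rows, columns=["edge_id", "x_um", "cell_flux_per_s",
                                        "density_cm", "velocity_cms",
                                        "sigma_p_dyncm2", "peak_portion"])
    return VesselSummary(table, pool, state, transport, decomps)


def run_amputation_experiment(config: AmputationConfig = AmputationConfig(),
                              seed: int = 0) -> AmputationComparison:
    """Intact vs amputated comparison on the default trunk topology.

    The activation threshold (0.975 quantile of pooled plasma WSS across
    intersegmental vessels) is computed on the intact run and applied to
    both runs so the peak-portion fold change is measured against a common
    reference.
    """
    fluid = net_mod.FluidParams(mu=config.mu_pas)
    intact = net_mod.build_trunk_network(
        n_se_pairs=config.n_se_pairs, da_length=config.da_length_um,
        se_length=config.se_length_um, se_radius=config.se_radius_um,
        trunk_radius=config.trunk_radius_um,
        alpha_c_profile=(config.alpha_c_head, config.alpha_c_tail))

    pre = _se_metrics(intact, fluid, config, seed)
    threshold = wss_mod.plasma_threshold(pre.plasma_pool)
    pre.apply_threshold(threshold)
    cut = net_mod.amputate(intact, config.n_distal_rungs)
    post = _se_metrics(cut, fluid, config, seed + 1)
    post.apply_threshold(threshold)
    return AmputationComparison(config, seed, threshold, pre, post)
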