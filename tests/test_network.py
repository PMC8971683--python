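import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microhemo import network as nm

MU = 1.0e-3


def series_pair(r1_um, r2_um):
    nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0), "c": (200.0, 0.0)}
    edges = [nm.VesselEdge("e1", "a", "b", 100.0, r1_um, 0.0, "DA"),
             nm.VesselEdge("e2", "b", "c", 150.0, r2_um, 0.0, "DA")]
    return nm.TrunkNetwork(nodes, edges,
                           nm.BoundaryConditions("a", "c", 80.0, 0.0))


class TestEdgeResistance:
    def test_zero_cells_is_pure_poiseuille(self, fluid):
        e = nm.VesselEdge("e", "a", "b", 100.0, 3.0, 1e15, "SeA")
        expected = 8.0 * MU * 100e-6 / (math.pi * (3e-6) ** 4)
        assert nm.edge_resistance(e, fluid, 0) == pytest.approx(expected, rel=1e-12)

    def test_hand_value(self, fluid):
        # 8 * 1e-3 * 1e-4 / (pi * (3e-6)^4), worked by hand
        e = nm.VesselEdge("e", "a", "b", 100.0, 3.0, 0.0, "SeA")
        assert nm.edge_resistance(e, fluid, 0) == pytest.approx(
            8e-7 / (math.pi * 8.1e-23), rel=1e-12)

    def test_linear_increment(self, fluid):
        e = nm.VesselEdge("e", "a", "b", 100.0, 3.0, 1e15, "SeA")
        base = nm.edge_resistance(e, fluid, 0)
        assert nm.edge_resistance(e, fluid, 2) == pytest.approx(base + 2e15, rel=1e-12)

    def test_negative_cells_rejected(self, fluid):
        e = nm.VesselEdge("e", "a", "b", 100.0, 3.0, 0.0, "SeA")
        with pytest.raises(nm.InvalidParameterError):
            nm.edge_resistance(e, fluid, -1)


class TestBuildTrunk:
    def test_edge_counts_three_rungs(self, trunk3):
        assert len(trunk3.edges_of_kind("SeA")) == 3
        assert len(trunk3.edges_of_kind("SeV")) == 3
        assert len(trunk3.edges_of_kind("ECL")) == 1

    def test_constant_alpha_profile(self):
        net = nm.build_trunk_network(n_se_pairs=4, alpha_c_profile=(7e14, 7e14))
        assert all(e.alpha_c == pytest.approx(7e14) for e in net.edges)

    def test_alpha_decreases_head_to_tail(self, trunk16):
        sea = sorted(trunk16.edges_of_kind("SeA"),
                     key=lambda e: trunk16.nodes[e.head_node][0])
        alphas = [e.alpha_c for e in sea]
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_sixteen_rungs_connected(self, trunk16):
        # independent graph-search oracle
        g = nx.Graph()
        for e in trunk16.edges:
            g.add_edge(e.head_node, e.tail_node)
        assert nx.has_path(g, "da_0", "pcv_0")

    @pytest.mark.parametrize("kwargs", [
        {"da_length": 0.0}, {"se_length": -1.0}, {"se_radius": 0.0},
        {"trunk_radius": -5.0}, {"n_se_pairs": 1},
    ])
    def test_invalid_geometry(self, kwargs):
        with pytest.raises(nm.InvalidParameterError):
            nm.build_trunk_network(**kwargs)


class TestSolveFlow:
    def test_parallel_identical_edges_split_equally(self, fluid):
        nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0)}
        edges = [nm.VesselEdge("p1", "a", "b", 100.0, 4.0, 0.0, "SeA"),
                 nm.VesselEdge("p2", "a", "b", 100.0, 4.0, 0.0, "SeA")]
        net = nm.TrunkNetwork(nodes, edges,
                              nm.BoundaryConditions("a", "b", 50.0, 0.0))
        st_ = nm.solve_flow(net, fluid)
        assert st_.edge_fluxes_m3s["p1"] == pytest.approx(
            st_.edge_fluxes_m3s["p2"], rel=1e-12)

    def test_series_hand_formula(self, fluid):
        net = series_pair(4.0, 3.0)
        st_ = nm.solve_flow(net, fluid)
        r1 = nm.edge_resistance(net.edge_map["e1"], fluid)
        r2 = nm.edge_resistance(net.edge_map["e2"], fluid)
        expected = 80.0 / (r1 + r2)
        for eid in ("e1", "e2"):
            assert st_.edge_fluxes_m3s[eid] == pytest.approx(expected, rel=1e-12)

    def test_parallel_hand_formula(self, fluid):
        nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0)}
        edges = [nm.VesselEdge("p1", "a", "b", 100.0, 4.0, 0.0, "SeA"),
                 nm.VesselEdge("p2", "a", "b", 180.0, 3.0, 0.0, "SeA")]
        net = nm.TrunkNetwork(nodes, edges,
                              nm.BoundaryConditions("a", "b", 50.0, 0.0))
        st_ = nm.solve_flow(net, fluid)
        for eid in ("p1", "p2"):
            expected = 50.0 / nm.edge_resistance(net.edge_map[eid], fluid)
            assert st_.edge_fluxes_m3s[eid] == pytest.approx(expected, rel=1e-12)

    def test_conservation_default_trunk(self, trunk3, fluid):
        st_ = nm.solve_flow(trunk3, fluid)
        assert st_.max_relative_residual < 1e-10

    def test_velocity_flux_consistency(self, trunk3, fluid):
        st_ = nm.solve_flow(trunk3, fluid)
        for e in trunk3.edges:
            v = st_.edge_fluxes_m3s[e.id] / (math.pi * (e.radius_um * 1e-6) ** 2)
            assert st_.edge_velocities_ms[e.id] == pytest.approx(v, rel=1e-12)

    def test_occlusion_raises_resistance_lowers_flux(self, fluid):
        net = series_pair(4.0, 3.0)
        free = nm.solve_flow(net, fluid)
        net.edge_map["e1"].alpha_c = 1e15
        loaded = nm.solve_flow(net, fluid, nm.RBCState([("e1", 10.0), ("e1", 50.0)]))
        assert abs(loaded.edge_fluxes_m3s["e1"]) < abs(free.edge_fluxes_m3s["e1"])

    def test_disconnected_graph_raises(self, fluid):
        nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0), "c": (0.0, 50.0),
                 "d": (100.0, 50.0)}
        edges = [nm.VesselEdge("e1", "a", "b", 100.0, 4.0, 0.0, "DA"),
                 nm.VesselEdge("e2", "c", "d", 100.0, 4.0, 0.0, "DA")]
        net = nm.TrunkNetwork(nodes, edges,
                              nm.BoundaryConditions("a", "d", 50.0, 0.0))
        with pytest.raises(nm.TopologyError):
            nm.solve_flow(net, fluid)


class TestPartitionRBC:
    def test_symmetric(self):
        assert nm.partition_rbc([1.0, 1.0], bias_exponent=3.0) == pytest.approx([0.5, 0.5])

    def test_flux_fraction_at_unit_exponent(self):
        assert nm.partition_rbc([3.0, 1.0], bias_exponent=1.0) == pytest.approx([0.75, 0.25])

    def test_quadratic_bias(self):
        assert nm.partition_rbc([3.0, 1.0], bias_exponent=2.0) == pytest.approx([0.9, 0.1])

    def test_all_zero_rejected(self):
        with pytest.raises(nm.UndefinedPartitionError):
            nm.partition_rbc([0.0, 0.0])

    def test_sub_unit_exponent_rejected(self):
        with pytest.raises(nm.InvalidParameterError):
            nm.partition_rbc([1.0, 2.0], bias_exponent=0.5)

    @given(q1=st.floats(0.1, 100.0), q2=st.floats(0.1, 100.0),
           beta=st.floats(1.0, 4.0))
    @settings(max_examples=100, deadline=None)
    def test_bias_exceeds_flux_fraction(self, q1, q2, beta):
        p = nm.partition_rbc([q1, q2], bias_exponent=beta)
        assert p.sum() == pytest.approx(1.0, rel=1e-12)
        big = int(np.argmax([q1, q2]))
        frac = max(q1, q2) / (q1 + q2)
        assert p[big] >= frac - 1e-12


class TestTransport:
    def test_single_path_traversal(self, fluid):
        nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0), "c": (200.0, 0.0)}
        edges = [nm.VesselEdge("e1", "a", "b", 100.0, 5.0, 0.0, "DA"),
                 nm.VesselEdge("e2", "b", "c", 100.0, 5.0, 0.0, "ECL")]
        net = nm.TrunkNetwork(nodes, edges,
                              nm.BoundaryConditions("a", "c", 100.0, 0.0))
        res = nm.simulate_rbc_transport(net, fluid, inflow_rate=10.0,
                                        duration=5.0, dt=0.05, seed=3)
        assert res.n_injected > 0
        assert res.edge_traversals["e1"] == res.n_injected
        assert res.edge_traversals["e2"] >= res.n_exited - 1  # last cells may be en route

    def test_deterministic_given_seed(self, y_network, fluid):
        kw = dict(inflow_rate=50.0, duration=3.0, dt=0.05,
                  bias_exponent=2.0, seed=11)
        a = nm.simulate_rbc_transport(y_network, fluid, **kw)
        b = nm.simulate_rbc_transport(y_network, fluid, **kw)
        assert a.trajectories.equals(b.trajectories)
        assert a.edge_series.equals(b.edge_series)

    def test_symmetric_branch_counts_binomial(self, y_network, fluid):
        res = nm.simulate_rbc_transport(y_network, fluid, inflow_rate=1000.0,
                                        duration=10.0, dt=0.05,
                                        bias_exponent=1.0, seed=7)
        n1 = res.edge_traversals["b1"]
        n2 = res.edge_traversals["b2"]
        n = n1 + n2
        assert n > 9000          # a few cells may still be in the stem at t_end
        sigma = math.sqrt(n * 0.25)
        assert abs(n1 - n / 2) < 3 * sigma

    def test_routing_fractions_match_flux_fractions(self, fluid):
        # asymmetric branches, exponent 1: long-run fractions ~ flux fractions
        nodes = {"i": (0.0, 0.0), "m": (100.0, 0.0), "x": (200.0, 50.0),
                 "y": (200.0, -50.0), "o": (300.0, 0.0)}
        edges = [nm.VesselEdge("in", "i", "m", 100.0, 6.0, 0.0, "DA"),
                 nm.VesselEdge("b1", "m", "x", 100.0, 5.0, 0.0, "SeA"),
                 nm.VesselEdge("b2", "m", "y", 100.0, 3.5, 0.0, "SeA"),
                 nm.VesselEdge("o1", "x", "o", 120.0, 5.0, 0.0, "SeV"),
                 nm.VesselEdge("o2", "y", "o", 120.0, 3.5, 0.0, "SeV")]
        net = nm.TrunkNetwork(nodes, edges,
                              nm.BoundaryConditions("i", "o", 100.0, 0.0))
        st_ = nm.solve_flow(net, fluid)
        frac = st_.edge_fluxes_m3s["b1"] / (st_.edge_fluxes_m3s["b1"]
                                            + st_.edge_fluxes_m3s["b2"])
        res = nm.simulate_rbc_transport(net, fluid, inflow_rate=1000.0,
                                        duration=10.0, dt=0.05,
                                        bias_exponent=1.0, seed=5)
        n1, n2 = res.edge_traversals["b1"], res.edge_traversals["b2"]
        n = n1 + n2
        sigma = math.sqrt(n * frac * (1 - frac))
        assert abs(n1 - n * frac) < 3 * sigma

    def test_expected_cell_flux_conserves_inflow(self, trunk3, fluid):
        st_ = nm.solve_flow(trunk3, fluid)
        cf = nm.expected_cell_flux(trunk3, st_, bias_exponent=2.0, inflow_rate=5.0)
        # everything injected leaves through edges touching the outlet
        outlet = trunk3.boundary.outlet_node
        into_outlet = sum(cf[e.id] for e in trunk3.edges
                          if outlet in (e.head_node, e.tail_node))
        assert into_outlet == pytest.approx(5.0, rel=1e-9)


class TestAmputate:
    def test_minimal_cut_removes_ecl_keeps_rungs(self, trunk16):
        cut = nm.amputate(trunk16, 0)
        assert not cut.edges_of_kind("ECL")
        assert len(cut.edges_of_kind("SeA")) == 16

    def test_two_rung_cut_counts(self, trunk16):
        cut = nm.amputate(trunk16, 2)
        assert len(cut.edges_of_kind("SeA")) == 14
        assert len(cut.edges_of_kind("SeV")) == 14

    def test_stubs_pruned(self, trunk16):
        cut = nm.amputate(trunk16, 2)
        degree = {}
        for e in cut.edges:
            degree[e.head_node] = degree.get(e.head_node, 0) + 1
            degree[e.tail_node] = degree.get(e.tail_node, 0) + 1
        bc = cut.boundary
        assert all(d >= 2 for n, d in degree.items()
                   if n not in (bc.inlet_node, bc.outlet_node))

    def test_nearest_sea_flux_increases(self, trunk16, fluid):
        pre = nm.solve_flow(trunk16, fluid)
        post = nm.solve_flow(nm.amputate(trunk16, 0), fluid)
        assert abs(post.edge_fluxes_m3s["SeA_16"]) > abs(pre.edge_fluxes_m3s["SeA_16"])

    def test_total_sea_flux_not_decreased(self, trunk16, fluid):
        pre = nm.solve_flow(trunk16, fluid)
        post = nm.solve_flow(nm.amputate(trunk16, 0), fluid)
        tot_pre = sum(abs(pre.edge_fluxes_m3s[e.id])
                      for e in trunk16.edges_of_kind("SeA"))
        tot_post = sum(abs(post.edge_fluxes_m3s[e.id])
                       for e in trunk16.edges_of_kind("SeA"))
        assert tot_post >= tot_pre

    def test_disconnecting_cut_raises(self):
        # outlet reachable only through the ECL
        nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0), "c": (200.0, 0.0),
                 "u": (100.0, 50.0), "o": (250.0, -30.0)}
        edges = [nm.VesselEdge("d1", "a", "b", 100.0, 5.0, 0.0, "DA"),
                 nm.VesselEdge("d2", "b", "c", 100.0, 5.0, 0.0, "DA"),
                 nm.VesselEdge("s1", "b", "u", 50.0, 3.0, 0.0, "SeA"),
                 nm.VesselEdge("s2", "u", "c", 120.0, 3.0, 0.0, "SeA"),
                 nm.VesselEdge("ecl", "c", "o", 60.0, 5.0, 0.0, "ECL")]
        net = nm.TrunkNetwork(nodes, edges,
                              nm.BoundaryConditions("a", "o", 100.0, 0.0))
        with pytest.raises(nm.TopologyError):
            nm.amputate(net, 0)

    def test_invalid_rung_count(self, trunk3):
        with pytest.raises(nm.InvalidParameterError):
            nm.amputate(trunk3, 3)


class TestAdaptRadii:
    def single_edge(self, radius_um=3.0):
        nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0)}
        e = nm.VesselEdge("e1", "a", "b", 100.0, radius_um, 0.0, "SeA")
        return nm.TrunkNetwork(nodes, [e],
                               nm.BoundaryConditions("a", "b", 100.0, 0.0))

    def test_fixed_point_unchanged(self, fluid):
        net = self.single_edge()
        st_ = nm.solve_flow(net, fluid)
        v_cms = abs(st_.edge_velocities_ms["e1"]) * 100.0
        sigma = 4.0 * fluid.mu * (v_cms / 100.0) / 3e-6 * 10.0
        res = nm.adapt_radii(net, fluid, None, set_point_dyncm2=sigma,
                             gain=0.5, max_iter=50, tol=1e-9)
        assert res.converged and res.n_iter == 1
        assert res.radius_trajectory_um["e1"][-1] == pytest.approx(3.0, rel=1e-12)

    def test_fixed_flux_closed_form(self, fluid):
        net = self.single_edge()
        st_ = nm.solve_flow(net, fluid)
        q = abs(st_.edge_fluxes_m3s["e1"])
        set_point = 5.0          # dyne/cm^2 = 0.5 Pa
        res = nm.adapt_radii(net, fluid, None, set_point_dyncm2=set_point,
                             gain=0.3, max_iter=500, tol=1e-9, resolve=False)
        closed = (4.0 * fluid.mu * q / (math.pi * 0.5)) ** (1.0 / 3.0) / 1e-6
        assert res.converged
        assert res.radius_trajectory_um["e1"][-1] == pytest.approx(closed, rel=1e-3)

    def test_monotone_growth_when_above_set_point(self, fluid):
        net = self.single_edge()
        st_ = nm.solve_flow(net, fluid)
        v_cms = abs(st_.edge_velocities_ms["e1"]) * 100.0
        sigma0 = 4.0 * fluid.mu * (v_cms / 100.0) / 3e-6 * 10.0
        # gain small enough that the multiplicative update cannot overshoot
        res = nm.adapt_radii(net, fluid, None, set_point_dyncm2=sigma0 / 2.0,
                             gain=0.1, max_iter=300, tol=1e-6, resolve=False)
        r = res.radius_trajectory_um["e1"]
        assert np.all(np.diff(r) > 0)

    def test_non_convergence_flagged(self, fluid):
        net = self.single_edge()
        res = nm.adapt_radii(net, fluid, None, set_point_dyncm2=1e-3,
                             gain=0.05, max_iter=3, tol=1e-12)
        assert not res.converged
        assert res.n_iter == 3

    @given(gain=st.floats(0.05, 0.5), set_point=st.floats(0.5, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_adaptation_convergence_property(self, gain, set_point):
        fluid = nm.FluidParams()
        net = self.single_edge()
        st_ = nm.solve_flow(net, fluid)
        q = abs(st_.edge_fluxes_m3s["e1"])
        res = nm.adapt_radii(net, fluid, None, set_point_dyncm2=set_point,
                             gain=gain, max_iter=3000, tol=1e-8, resolve=False)
        closed = (4.0 * fluid.mu * q
                  / (math.pi * set_point / 10.0)) ** (1.0 / 3.0) / 1e-6
        assert res.converged
        assert res.radius_trajectory_um["e1"][-1] == pytest.approx(closed, rel=1e-3)


class TestJsonRoundTrip:
    def test_round_trip(self, trunk3):
        text = nm.network_to_json(trunk3)
        back = nm.network_from_json(text)
        assert back.nodes == trunk3.nodes
        assert len(back.edges) == len(trunk3.edges)
        for a, b in zip(sorted(trunk3.edges, key=lambda e: e.id),
                        sorted(back.edges, key=lambda e: e.id)):
            assert (a.id, a.head_node, a.tail_node, a.kind) == \
                (b.id, b.head_node, b.tail_node, b.kind)
            assert a.length_um == pytest.approx(b.length_um)
            assert a.alpha_c == pytest.approx(b.alpha_c)

    def test_bad_schema_rejected(self):
        with pytest.raises(nm.InvalidParameterError):
            nm.network_from_json('{"schema": "other/9", "nodes": [], '
                                 '"edges": [], "boundary": {}}')
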