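"""Topological indices and the two-stage median-multiple screen.

networkx serves purely as the independent reference implementation; every
production number comes from the package's own graph code.
"""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from netpharm.graph_io import Network
from netpharm.ppi_centrality import (
    INDEX_NAMES,
    compute_centralities,
    expand_subnetwork,
    intersect_networks,
    median_multiple_threshold,
    two_stage_screen,
)
from netpharm.synthetic_data import SyntheticConfig, generate_interactome
from netpharm.target_assembly import TargetSet

from .conftest import make_network, random_network


def to_nx(net):
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)
    return g


def seeds(*symbols):
    ts = TargetSet()
    for s in symbols:
        ts.add(s, "seed")
    return ts


class TestExpandSubnetwork:
    def test_leaf_seed_on_star(self, star4):
        sub = expand_subnetwork(star4, seeds("L1"))
        assert sub.nodes == {"L1", "C0"}
        assert sub.n_edges == 1

    def test_center_seed_on_star(self, star4):
        sub = expand_subnetwork(star4, seeds("C0"))
        assert sub.n_nodes == 5 and sub.n_edges == 4

    def test_missing_seeds_reported_not_included(self, star4):
        sub = expand_subnetwork(star4, seeds("C0", "ZZZ"))
        assert "ZZZ" not in sub.nodes
        assert sub.missing_seeds == ["ZZZ"]

    def test_all_seeds_missing_error(self, star4):
        with pytest.raises(ValueError):
            expand_subnetwork(star4, seeds("X", "Y"))

    def test_against_bfs_depth1_oracle(self, rng):
        cfg = SyntheticConfig(seed=7, n_nodes=1500, complex_count=20)
        net, _ = generate_interactome(cfg)
        picked = rng.choice(sorted(net.nodes), size=388, replace=False)
        sub = expand_subnetwork(net, seeds(*picked))
        g = to_nx(net)
        keep = set(picked)
        for s in picked:
            keep |= set(g.neighbors(s))
        oracle = g.subgraph(keep)
        assert sub.n_nodes == oracle.number_of_nodes()
        assert sub.n_edges == oracle.number_of_edges()

    def test_depth_zero_is_induced_on_seeds(self, triangle):
        sub = expand_subnetwork(triangle, seeds("A", "B"), depth=0)
        assert sub.nodes == {"A", "B"} and sub.n_edges == 1


class TestIntersectNetworks:
    def test_idempotent(self, triangle):
        out = intersect_networks(triangle, triangle)
        assert out.nodes == triangle.nodes and out.edges == triangle.edges

    def test_disjoint(self, triangle):
        other = make_network([("X", "Y")])
        out = intersect_networks(triangle, other)
        assert out.n_nodes == 0 and out.n_edges == 0

    def test_against_set_oracle(self, rng):
        parent = random_network(rng, 60, 0.1)
        nodes = sorted(parent.nodes)
        a = parent.induced_subgraph(rng.choice(nodes, size=40, replace=False))
        b = parent.induced_subgraph(rng.choice(nodes, size=40, replace=False))
        out = intersect_networks(a, b)
        assert out.nodes == a.nodes & b.nodes
        assert out.edges == a.edges & b.edges


class TestClosedFormCentralities:
    def test_path(self, path3):
        tab = compute_centralities(path3)
        assert tab.values["BC"]["B"] == 1.0
        assert tab.values["BC"]["A"] == 0.0
        assert tab.values["CC"]["B"] == 1.0
        assert tab.values["DC"]["B"] == 2.0
        assert tab.values["CC"]["A"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("k", [4, 6, 9])
    def test_star(self, k):
        net = make_network([("HUB", f"L{i}") for i in range(k)])
        tab = compute_centralities(net)
        assert tab.values["BC"]["HUB"] == math.comb(k, 2)
        assert tab.values["LAC"]["HUB"] == 0.0
        # star eigenvector solved analytically: center 1/sqrt(2), leaves equal
        assert tab.values["EC"]["HUB"] == pytest.approx(1 / math.sqrt(2), abs=1e-8)
        assert tab.values["EC"]["L0"] == pytest.approx(1 / math.sqrt(2 * k), abs=1e-8)

    def test_triangle_worked_values(self, triangle):
        tab = compute_centralities(triangle)
        for v in "ABC":
            assert tab.values["LAC"][v] == 1.0
            assert tab.values["NC"][v] == 2.0
            assert tab.values["CC"][v] == 1.0
            assert tab.values["EC"][v] == pytest.approx(1 / math.sqrt(3), abs=1e-10)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph(self, n):
        # K_n: all indices constant; each edge's ECC is 1 so NC(v) = n-1
        names = [f"V{i}" for i in range(n)]
        net = make_network(itertools.combinations(names, 2))
        tab = compute_centralities(net)
        for v in names:
            assert tab.values["DC"][v] == n - 1
            assert tab.values["BC"][v] == 0.0
            assert tab.values["CC"][v] == 1.0
            assert tab.values["LAC"][v] == n - 2
            assert tab.values["NC"][v] == n - 1
            assert tab.values["EC"][v] == pytest.approx(1 / math.sqrt(n), abs=1e-10)

    def test_isolated_node_conventions(self):
        net = make_network([("A", "B")], extra_nodes=["Z"])
        tab = compute_centralities(net)
        assert tab.values["CC"]["Z"] == 0.0
        assert tab.values["EC"]["Z"] == 0.0
        assert tab.values["LAC"]["Z"] == 0.0
        assert tab.values["NC"]["Z"] == 0.0


def brute_force_lac(net):
    adj = net.adjacency()
    out = {}
    for v in net.nodes:
        nbrs = adj[v]
        if not nbrs:
            out[v] = 0.0
            continue
        induced_deg = {u: len(adj[u] & nbrs) for u in nbrs}
        out[v] = sum(induced_deg.values()) / len(nbrs)
    return out


def brute_force_nc(net):
    adj = net.adjacency()
    out = {}
    for v in net.nodes:
        total = 0.0
        for u in adj[v]:
            denom = min(len(adj[v]) - 1, len(adj[u]) - 1)
            if denom > 0:
                total += len(adj[v] & adj[u]) / denom
        out[v] = total
    return out


class TestReferenceAgreement:
    def test_fifty_er_graphs_match_reference(self):
        """DC/BC/CC/EC vs networkx and LAC/NC vs brute force, 1e-8."""
        master = np.random.default_rng(42)
        for rep in range(50):
            n = int(master.integers(5, 31))
            p = float(master.uniform(0.08, 0.5))
            net = random_network(master, n, p)
            tab = compute_centralities(net)
            g = to_nx(net)
            bc = nx.betweenness_centrality(g, normalized=False)
            cc = nx.closeness_centrality(g, wf_improved=False)
            deg = dict(g.degree())
            for v in net.nodes:
                assert tab.values["DC"][v] == deg[v]
                assert tab.values["BC"][v] == pytest.approx(bc[v], abs=1e-8)
                assert tab.values["CC"][v] == pytest.approx(cc[v], abs=1e-8)
            # EC per connected component, compared up to sign against a
            # dense symmetric eigendecomposition
            for comp in nx.connected_components(g):
                if len(comp) == 1:
                    continue
                order = sorted(comp)
                a = nx.to_numpy_array(g, nodelist=order)
                w, vecs = np.linalg.eigh(a)
                vec = np.abs(vecs[:, np.argmax(w)])
                vec /= np.linalg.norm(vec)
                mine = np.array([tab.values["EC"][v] for v in order])
                np.testing.assert_allclose(mine, vec, atol=1e-8)
            lac = brute_force_lac(net)
            ncv = brute_force_nc(net)
            for v in net.nodes:
                assert tab.values["LAC"][v] == pytest.approx(lac[v], abs=1e-8)
                assert tab.values["NC"][v] == pytest.approx(ncv[v], abs=1e-8)

    def test_bc_against_path_enumeration(self, rng):
        """Brandes accumulation equals explicit all-shortest-path counting, n<=12."""
        for _ in range(10):
            net = random_network(rng, int(rng.integers(5, 13)), 0.35)
            tab = compute_centralities(net)
            g = to_nx(net)
            bc = dict.fromkeys(net.nodes, 0.0)
            for s, t in itertools.combinations(sorted(net.nodes), 2):
                if not nx.has_path(g, s, t):
                    continue
                paths = list(nx.all_shortest_paths(g, s, t))
                for path in paths:
                    for v in path[1:-1]:
                        bc[v] += 1.0 / len(paths)
            for v in net.nodes:
                assert tab.values["BC"][v] == pytest.approx(bc[v], abs=1e-9)

    def test_ec_constant_on_vertex_transitive_graph(self):
        cycle = make_network([(f"V{i}", f"V{(i + 1) % 9}") for i in range(9)])
        tab = compute_centralities(cycle)
        values = list(tab.values["EC"].values())
        assert np.allclose(values, values[0], atol=1e-8)


class TestMedianMultipleThreshold:
    def test_even_list(self):
        assert median_multiple_threshold([1, 1, 2, 3, 5, 8]) == 5.0

    def test_single_value_doubles(self):
        # a lone median of 29 gives the printed primary cutoff of 58
        assert median_multiple_threshold([29]) == 58.0

    def test_constant_list(self):
        assert median_multiple_threshold([7, 7, 7], multiplier=2) == 14.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            median_multiple_threshold([])


class TestTwoStageScreen:
    def test_star_keeps_center(self):
        net = make_network([("HUB", f"L{i}") for i in range(10)])
        rep = two_stage_screen(net)
        assert rep.stage1_threshold == 2.0
        assert rep.hub_network.nodes == {"HUB"}
        # single-node hub network: all medians from that node, so it stays
        assert rep.core_network.nodes == {"HUB"}

    def test_regular_graph_errors(self):
        cycle = make_network([(f"V{i}", f"V{(i + 1) % 8}") for i in range(8)])
        with pytest.raises(ValueError, match="stage-1"):
            two_stage_screen(cycle)

    def test_zero_multiplier_keeps_everything(self, triangle):
        rep = two_stage_screen(triangle, multiplier=0.0)
        assert rep.hub_network.nodes == triangle.nodes
        assert rep.core_network.nodes == triangle.nodes

    def test_self_consistency_on_generated_networks(self):
        """Thresholds re-derive from emitted tables; core passes recheck; nesting."""
        for seed in (11, 12, 13):
            net, manifest = generate_interactome(SyntheticConfig(seed=seed))
            rep = two_stage_screen(net)
            dc_full = [rep.stage1_table.values["DC"][v] for v in rep.stage1_table.nodes]
            assert rep.stage1_threshold == 2 * np.median(dc_full)
            for idx in INDEX_NAMES:
                col = rep.stage2_table.column(idx)
                assert rep.stage2_thresholds[idx] == pytest.approx(2 * np.median(col))
            for v in rep.core_network.nodes:
                for idx in INDEX_NAMES:
                    assert rep.stage2_table.values[idx][v] >= rep.stage2_thresholds[idx]
            assert rep.core_network.nodes <= rep.hub_network.nodes <= net.nodes
            assert set(manifest["planted_hubs"]) <= rep.hub_network.nodes

    def test_invariant_under_relabeling(self, rng):
        net = random_network(rng, 40, 0.2)
        mapping = {v: f"X{i:03d}" for i, v in enumerate(sorted(net.nodes)[::-1])}
        relabeled = Network()
        for v in net.nodes:
            relabeled.add_node(mapping[v])
        for a, b in net.edges:
            relabeled.add_edge(mapping[a], mapping[b])
        try:
            rep = two_stage_screen(net)
        except ValueError:
            with pytest.raises(ValueError):
                two_stage_screen(relabeled)
            return
        rep2 = two_stage_screen(relabeled)
        assert {mapping[v] for v in rep.hub_network.nodes} == rep2.hub_network.nodes
        assert {mapping[v] for v in rep.core_network.nodes} == rep2.core_network.nodes
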