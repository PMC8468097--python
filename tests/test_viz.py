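"""Hub filtering, force-directed layout, role assignment and rendering."""

import json
import math
import random

import networkx as nx
import pytest

from conftest import as_network

from communet.errors import ContractError
from communet.seeds import EnvironmentalProxy
from communet.viz import (
    NetworkLayout,
    Palette,
    assign_roles,
    filter_hubs,
    layout_network,
    render,
)


def star(n_leaves):
    g = nx.DiGraph()
    for i in range(n_leaves):
        if i % 2:
            g.add_edge("hub", f"L{i}")
        else:
            g.add_edge(f"L{i}", "hub")
    return as_network(g)


class TestFilterHubs:
    def test_26_neighbors_removed(self):
        net = filter_hubs(star(26), max_neighbors=25)
        assert "hub" not in net.nodes

    def test_25_neighbors_retained(self):
        net = filter_hubs(star(25), max_neighbors=25)
        assert "hub" in net.nodes
        assert len(net.edges) == 25

    def test_in_plus_out_to_same_neighbor_counts_once(self):
        g = nx.DiGraph([("A", "B"), ("B", "A"), ("A", "C")])
        net = filter_hubs(as_network(g), max_neighbors=2)
        assert net.nodes == {"A", "B", "C"}

    def test_single_pass_no_cascade(self):
        # hub1 has 4 neighbors, hub2 has 3; removing hub1 would drop hub2 to
        # 2, but degrees are measured on the input graph only
        g = nx.DiGraph()
        g.add_edges_from([("hub1", x) for x in ("a", "b", "c", "hub2")])
        g.add_edges_from([("hub2", x) for x in ("d", "e")])
        net = filter_hubs(as_network(g), max_neighbors=3)
        assert "hub1" not in net.nodes and "hub2" in net.nodes

    def test_matches_degree_scan_oracle(self, rng):
        from conftest import random_digraph

        for _ in range(20):
            g = random_digraph(rng, n_max=60)
            threshold = rng.randint(1, 8)
            und = g.to_undirected()
            expected = {n for n in g.nodes if und.degree(n) <= threshold}
            net = filter_hubs(as_network(g), max_neighbors=threshold)
            assert net.nodes == expected

    def test_threshold_contract(self):
        with pytest.raises(ContractError):
            filter_hubs(star(3), max_neighbors=0)


class TestLayout:
    def path_net(self, n=10):
        g = nx.path_graph(n, create_using=nx.DiGraph)
        g = nx.relabel_nodes(g, {i: f"C{i}" for i in range(n)})
        return as_network(g)

    def test_deterministic_for_fixed_seed(self):
        net = self.path_net()
        assert layout_network(net, 2, 50, 7) == layout_network(net, 2, 50, 7)

    def test_different_seeds_differ(self):
        net = self.path_net()
        assert layout_network(net, 2, 50, 1) != layout_network(net, 2, 50, 2)

    def test_zero_iterations_is_initial_placement(self):
        net = self.path_net()
        pos = layout_network(net, 2, 0, 3)
        assert set(pos) == net.nodes
        assert all(math.isfinite(x) for p in pos.values() for x in p)

    def test_three_dimensional_positions(self):
        pos = layout_network(self.path_net(), 3, 20, 0)
        assert all(len(p) == 3 for p in pos.values())

    def test_forces_spread_path_endpoints(self):
        net = self.path_net(12)
        pos = layout_network(net, 2, 50, 0)

        def dist(a, b):
            return math.dist(pos[a], pos[b])

        assert dist("C0", "C11") > dist("C0", "C1")

    def test_empty_network(self):
        assert layout_network(as_network(nx.DiGraph()), 2, 50, 0) == {}

    def test_dims_contract(self):
        with pytest.raises(ContractError):
            layout_network(self.path_net(), 4, 10, 0)


class TestAssignRoles:
    def net(self):
        g = nx.DiGraph()
        g.add_edge("C1", "C2", witnesses={("R1", "1.1.1.1")})
        g.add_edge("C2", "C3", witnesses={("R2", "2.2.2.2")})
        from communet.netgraph import MetabolicNetwork

        return MetabolicNetwork(graph=g, scope_label="treatment_1")

    def proxy(self, compounds):
        return EnvironmentalProxy(
            compounds=set(compounds),
            provenance={c: (0, 1) for c in compounds},
            scope_label="treatment_1",
        )

    def test_three_way_classification(self):
        node_roles, edge_roles = assign_roles(
            self.net(), self.proxy({"C1"}), {"C3"}, {"1.1.1.1"}
        )
        assert node_roles == {"C1": "seed", "C2": "shared", "C3": "treatment_unique"}
        assert edge_roles == {
            ("C1", "C2"): "differential", ("C2", "C3"): "background",
        }

    def test_empty_sets_all_shared(self):
        node_roles, edge_roles = assign_roles(self.net(), self.proxy(set()), set(), set())
        assert set(node_roles.values()) == {"shared"}
        assert set(edge_roles.values()) == {"background"}

    def test_seed_wins_over_unique(self):
        node_roles, _ = assign_roles(self.net(), self.proxy({"C1"}), {"C1"}, set())
        assert node_roles["C1"] == "seed"

    def test_role_counts_match_membership_oracle(self, rng):
        from conftest import random_digraph

        for _ in range(15):
            g = random_digraph(rng, n_max=40)
            net = as_network(g)
            nodes = sorted(g.nodes)
            seeds = set(rng.sample(nodes, len(nodes) // 4))
            unique = set(rng.sample(nodes, len(nodes) // 4))
            node_roles, _ = assign_roles(net, self.proxy(seeds), unique, set())
            for n in nodes:
                expected = (
                    "seed" if n in seeds
                    else "treatment_unique" if n in unique
                    else "shared"
                )
                assert node_roles[n] == expected


class TestRender:
    def layout_for(self, net, halos=None):
        pos = layout_network(net, 2, 10, 0)
        return NetworkLayout(
            positions=pos,
            node_roles={n: "shared" for n in pos},
            edge_roles={e: "background" for e in net.graph.edges},
            halo_pathways=halos or {},
            edges=sorted(net.graph.edges),
            scope_label="treatment_1",
        )

    def test_empty_network_placeholder_no_crash(self, tmp_path):
        layout = NetworkLayout(positions={}, node_roles={}, edge_roles={})
        files = render(layout, tmp_path, "empty")
        assert (tmp_path / "empty_network.png").exists()

    def test_halo_node_rendered_and_exported(self, tmp_path):
        g = nx.DiGraph()
        g.add_node("C1")
        net = as_network(g)
        layout = self.layout_for(net, halos={"C1": {"P1"}})
        render(layout, tmp_path, "t1", enriched_pathways=["P1"])
        export = json.loads((tmp_path / "3D_network_t1.json").read_text())
        assert export["nodes"][0]["halo_pathways"] == ["P1"]

    def test_per_pathway_subgraph_files_indexed(self, tmp_path):
        g = nx.DiGraph([("C1", "C2")])
        net = as_network(g)
        halos = {"C1": {"Alpha pathway", "Beta pathway"}, "C2": {"Beta pathway"}}
        layout = self.layout_for(net, halos=halos)
        render(layout, tmp_path, "t1",
               enriched_pathways=["Beta pathway", "Alpha pathway"])
        assert (tmp_path / "3D_network_t1_0_Alpha_pathway.json").exists()
        assert (tmp_path / "3D_network_t1_1_Beta_pathway.json").exists()
        beta = json.loads((tmp_path / "3D_network_t1_1_Beta_pathway.json").read_text())
        assert {n["id"] for n in beta["nodes"]} == {"C1", "C2"}
        assert beta["edges"] == [{"source": "C1", "target": "C2", "role": "background"}]

    def test_coordinate_export_byte_identical_across_calls(self, tmp_path):
        g = nx.DiGraph([("C1", "C2"), ("C2", "C3")])
        net = as_network(g)
        layout = self.layout_for(net)
        render(layout, tmp_path / "a", "x")
        render(layout, tmp_path / "b", "x")
        assert (tmp_path / "a" / "3D_network_x.json").read_bytes() == (
            tmp_path / "b" / "3D_network_x.json"
        ).read_bytes()
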