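import math

import networkx as nx
import numpy as np
import pytest

from dkgm import (
    Network,
    bfs_distances,
    load_edge_list,
    network_stats,
    random_graph,
)

from conftest import TOY_DEGREES, by_label
from oracles import adj_dict, bfs_dict


class TestLoadEdgeList:
    def test_duplicate_edges_collapse(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("a b\nb c\nb a\n")
        net = load_edge_list(p)
        assert (net.N, net.M) == (3, 2)

    def test_self_loops_dropped(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("1 1\n1 2\n")
        net = load_edge_list(p)
        assert (net.N, net.M) == (2, 1)

    def test_toy_fixture_file(self, toy_file):
        net = load_edge_list(toy_file)
        assert (net.N, net.M) == (9, 13)
        assert by_label(net, net.degrees) == TOY_DEGREES

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("# header\n\na b extra tokens ignored\n")
        assert load_edge_list(p).M == 1

    def test_single_token_line_names_line_number(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("a b\nlonely\n")
        with pytest.raises(ValueError, match=":2"):
            load_edge_list(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            load_edge_list(tmp_path / "nope.txt")

    def test_labels_first_appearance_order(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("z a\na q\n")
        assert load_edge_list(p).node_labels == ["z", "a", "q"]


class TestNetworkInvariants:
    def test_degree_sum_is_twice_edges(self, toy):
        assert toy.degrees.sum() == 2 * toy.M

    def test_adjacency_symmetric(self, toy):
        for i, j in toy.edges():
            assert i in toy.adjacency[j] and j in toy.adjacency[i]

    def test_networkx_round_trip(self, toy):
        g = toy.to_networkx()
        back = Network.from_networkx(g)
        assert sorted(back.edges()) == sorted(toy.edges())


class TestBfsDistances:
    def test_toy_neighborhood_orders_of_node_3(self, toy):
        src = toy.index_of("3")
        d = bfs_distances(toy, src, radius=2)
        one = {toy.node_labels[i] for i, h in d.items() if h == 1}
        two = {toy.node_labels[i] for i, h in d.items() if h == 2}
        assert one == {"2", "4", "7"}
        assert two == {"1", "5", "6"}
        assert d[src] == 0

    def test_path_unbounded(self):
        net = Network.from_edges([("a", "b"), ("b", "c")])
        d = bfs_distances(net, net.index_of("a"))
        assert d == {0: 0, 1: 1, 2: 2}

    def test_unreachable_nodes_absent(self):
        net = Network.from_edges([("a", "b"), ("c", "d")])
        d = bfs_distances(net, net.index_of("a"))
        assert set(d) == {net.index_of("a"), net.index_of("b")}

    def test_invalid_source(self, toy):
        with pytest.raises(IndexError):
            bfs_distances(toy, 99)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dict_bfs_oracle_on_random_graphs(self, seed):
        net = random_graph("er", 25, rng_seed=seed, p=0.12)
        adj = adj_dict(net)
        for src in range(net.N):
            assert bfs_distances(net, src) == bfs_dict(adj, src)

    def test_radius_truncation_is_prefix_of_full_bfs(self, toy):
        full = bfs_distances(toy, 0)
        trunc = bfs_distances(toy, 0, radius=1)
        assert trunc == {k: v for k, v in full.items() if v <= 1}


class TestNetworkStats:
    def test_triangle(self):
        s = network_stats(Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")]))
        assert s.clustering == 1.0
        assert s.mean_distance == 1.0
        assert s.heterogeneity == 1.0

    def test_star_k14(self):
        net = Network.from_edges([("h", f"l{i}") for i in range(4)])
        s = network_stats(net)
        assert s.clustering == 0.0
        assert s.assortativity == pytest.approx(-1.0)

    def test_toy_mean_degree(self, toy):
        assert network_stats(toy).mean_degree == pytest.approx(26 / 9)

    def test_complete_graph(self):
        net = Network.from_networkx(nx.complete_graph(6))
        s = network_stats(net)
        assert s.mean_distance == 1.0
        assert s.clustering == 1.0
        assert s.heterogeneity == 1.0

    def test_disconnected_mean_distance_over_reachable_pairs(self):
        net = Network.from_edges([("a", "b"), ("c", "d")])
        with pytest.warns(UserWarning):  # beta_c undefined on a matching
            assert network_stats(net).mean_distance == 1.0

    def test_edgeless_graph_warns_nan(self):
        net = Network.from_edges([], extra_nodes=["a", "b"])
        with pytest.warns(UserWarning):
            s = network_stats(net)
        assert math.isnan(s.assortativity)
        assert math.isnan(s.epidemic_threshold)

    def test_relabeling_leaves_stats_unchanged(self):
        net = random_graph("er", 20, rng_seed=3, p=0.2)
        rng = np.random.default_rng(0)
        perm = {lab: f"x{k}" for lab, k in
                zip(net.node_labels, rng.permutation(net.N))}
        relabeled = Network.from_edges(
            [(perm[net.node_labels[i]], perm[net.node_labels[j]])
             for i, j in net.edges()],
            extra_nodes=[perm[l] for l in net.node_labels],
        )
        a, b = network_stats(net), network_stats(relabeled)
        for f in ("N", "M", "mean_degree", "mean_distance", "clustering",
                  "assortativity", "heterogeneity", "epidemic_threshold"):
            assert getattr(a, f) == pytest.approx(getattr(b, f))

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            network_stats(Network.from_edges([], extra_nodes=["a"]))
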