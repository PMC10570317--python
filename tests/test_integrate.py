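"""Network merging, core reconstruction and hub ranking."""

import networkx as nx
import numpy as np
import pytest

from stressgcn.gcn import CoexpressionNetwork
from stressgcn.integrate import (
    first_neighbors,
    merge_networks,
    reconstruct_core,
    shared_edge_decomposition,
)


def make_net(edges, source, nodes=None, r=0.95, r_threshold=0.9, mode="signed",
             tf_nodes=(), go_nodes=()):
    g = nx.Graph()
    for n in nodes or set().union(*[set(e) for e in edges]) if (edges or nodes) else []:
        g.add_node(
            n,
            is_tf=n in tf_nodes,
            go_terms=frozenset({"GO:0050896"}) if n in go_nodes else frozenset(),
            source_conditions=frozenset({source}),
        )
    for u, v in edges:
        g.add_edge(
            u, v, r=r, r_by_source={source: r}, source_conditions=frozenset({source})
        )
    for n in g.nodes:
        g.nodes[n].setdefault("is_tf", False)
        g.nodes[n].setdefault("go_terms", frozenset())
        g.nodes[n].setdefault("source_conditions", frozenset({source}))
    return CoexpressionNetwork(graph=g, r_threshold=r_threshold, mode=mode)


def random_net(rng, source, n_nodes=30, p=0.1):
    nodes = [f"g{i}" for i in rng.choice(60, size=n_nodes, replace=False)]
    edges = [
        (a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
        if rng.random() < p
    ]
    used = sorted({n for e in edges for n in e})
    return make_net(edges, source, nodes=used)


class TestMerge:
    def test_idempotent_union(self):
        net = make_net([("a", "b"), ("b", "c")], "cond1")
        merged = merge_networks([net, net])
        assert merged.edge_set() == net.edge_set()
        assert set(merged.graph.nodes) == set(net.graph.nodes)

    def test_disjoint_edge_counts_add(self):
        n1 = make_net([("a", "b")], "c1")
        n2 = make_net([("x", "y")], "c2")
        merged = merge_networks([n1, n2])
        assert merged.n_edges == 2
        assert merged.graph.edges["a", "b"]["source_conditions"] == {"c1"}

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(1)
        nets = [random_net(rng, f"c{i}") for i in range(4)]
        merged = merge_networks(nets)
        assert set(merged.graph.nodes) == set().union(*[set(n.graph.nodes) for n in nets])
        assert merged.edge_set() == set().union(*[n.edge_set() for n in nets])
        for node in merged.graph.nodes:
            expected = {f"c{i}" for i, n in enumerate(nets) if node in n.graph.nodes}
            assert merged.graph.nodes[node]["source_conditions"] == expected
        for u, v in merged.graph.edges:
            expected = {
                f"c{i}"
                for i, n in enumerate(nets)
                if frozenset((u, v)) in n.edge_set()
            }
            assert merged.graph.edges[u, v]["source_conditions"] == expected

    def test_associative_commutative_on_sets(self):
        rng = np.random.default_rng(2)
        a, b, c = (random_net(rng, s) for s in ("c1", "c2", "c3"))
        left = merge_networks([merge_networks([a, b]), c])
        right = merge_networks([a, merge_networks([b, c])])
        swapped = merge_networks([c, a, b])
        for other in (right, swapped):
            assert left.edge_set() == other.edge_set()
            assert set(left.graph.nodes) == set(other.graph.nodes)

    def test_parameter_mismatch_rejected(self):
        n1 = make_net([("a", "b")], "c1", r_threshold=0.9)
        n2 = make_net([("a", "b")], "c2", r_threshold=0.8)
        with pytest.raises(ValueError, match="parameters"):
            merge_networks([n1, n2])

    def test_shared_only_filter(self):
        n1 = make_net([("a", "b"), ("a", "c")], "c1")
        n2 = make_net([("a", "b"), ("b", "d")], "c2")
        merged = merge_networks([n1, n2], shared_only=2)
        assert set(merged.graph.nodes) == {"a", "b"}
        assert merged.edge_set() == {frozenset(("a", "b"))}


class TestFirstNeighbors:
    def test_isolated_seed(self):
        net = make_net([("a", "b")], "c1")
        net.graph.add_node("z", is_tf=False, go_terms=frozenset(),
                           source_conditions=frozenset({"c1"}))
        assert first_neighbors(net, {"z"}) == {"z"}

    def test_path(self):
        net = make_net([("a", "b"), ("b", "c")], "c1")
        assert first_neighbors(net, {"a"}) == {"a", "b"}

    def test_matches_edge_scan(self):
        rng = np.random.default_rng(3)
        net = random_net(rng, "c1", n_nodes=40, p=0.15)
        nodes = sorted(net.graph.nodes)
        seeds = set(nodes[:10])
        expected = set(seeds)
        for u, v in net.graph.edges:
            if u in seeds:
                expected.add(v)
            if v in seeds:
                expected.add(u)
        assert first_neighbors(net, seeds) == expected

    def test_unknown_seed_named(self):
        net = make_net([("a", "b")], "c1")
        with pytest.raises(ValueError, match="ghost"):
            first_neighbors(net, {"ghost"})


class TestReconstructCore:
    def test_star_graph(self):
        edges = [("hub", f"leaf{i}") for i in range(5)]
        leaves = [f"leaf{i}" for i in range(5)]
        net = make_net(edges, "c1", tf_nodes={"hub"}, go_nodes={"hub", *leaves})
        core = reconstruct_core(net, {"hub"}, go_filter={"GO:0050896"})
        assert set(core.graph.nodes) == {"hub", *leaves}
        assert core.hub_ranking[0][0] == "hub"
        assert core.hub_ranking[0][1] == 5

    def test_seed_alone_when_neighbors_unlabelled(self):
        net = make_net([("tf1", "x"), ("tf1", "y")], "c1",
                       tf_nodes={"tf1"}, go_nodes={"tf1"})
        core = reconstruct_core(net, {"tf1"}, go_filter={"GO:0050896"})
        assert set(core.graph.nodes) == {"tf1"}
        assert core.n_edges == 0

    def test_no_filter_all_tfs_returns_full_network(self):
        rng = np.random.default_rng(4)
        net = random_net(rng, "c1")
        core = reconstruct_core(net, set(net.graph.nodes), go_filter=None)
        assert set(core.graph.nodes) == set(net.graph.nodes)
        assert core.as_network().edge_set() == net.edge_set()

    def test_core_is_subgraph_of_parent(self):
        rng = np.random.default_rng(5)
        net = random_net(rng, "c1")
        nodes = sorted(net.graph.nodes)
        for n in nodes[:5]:
            net.graph.nodes[n]["is_tf"] = True
            net.graph.nodes[n]["go_terms"] = frozenset({"GO:0050896"})
        for n in nodes[5:15]:
            net.graph.nodes[n]["go_terms"] = frozenset({"GO:0050896"})
        core = reconstruct_core(net, set(nodes[:5]), go_filter={"GO:0050896"})
        assert set(core.graph.nodes) <= set(net.graph.nodes)
        assert core.as_network().edge_set() <= net.edge_set()
        for node in core.graph.nodes:
            assert node in core.seed_tfs or any(
                core.graph.has_edge(node, s) or net.graph.has_edge(node, s)
                for s in core.seed_tfs
            )

    def test_no_tfs_error(self):
        net = make_net([("a", "b")], "c1")
        with pytest.raises(ValueError, match="no annotated TFs"):
            reconstruct_core(net, {"zz"})

    def test_hub_ranking_sorted_with_lexicographic_ties(self):
        net = make_net([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")], "c1",
                       tf_nodes={"a"})
        core = reconstruct_core(net, set(net.graph.nodes))
        degrees = [d for _g, d, _t in core.hub_ranking]
        assert degrees == sorted(degrees, reverse=True)
        tied = [g for g, d, _t in core.hub_ranking if d == 2]
        assert tied == sorted(tied)

    def test_planted_hubs_rank_first_among_module_tfs(self):
        """In the GO-filtered core of an integrated synthetic network,
        planted hub TFs outrank the other TFs of their modules."""
        from stressgcn.benchmarks import run_once

        _recalls, _fdps, hub_first = run_once(7)
        assert len(hub_first) == 3
        assert sum(hub_first) >= 2


class TestSharedEdgeDecomposition:
    def test_single_source(self):
        net = make_net([("a", "b"), ("b", "c")], "c1")
        cells = shared_edge_decomposition(net)
        assert cells == {frozenset({"c1"}): 2}

    def test_one_shared_edge(self):
        n1 = make_net([("a", "b"), ("a", "c")], "c1")
        n2 = make_net([("a", "b"), ("b", "d")], "c2")
        cells = shared_edge_decomposition(merge_networks([n1, n2]))
        assert cells[frozenset({"c1", "c2"})] == 1
        assert sum(cells.values()) == 3

    def test_matches_membership_oracle(self):
        rng = np.random.default_rng(6)
        nets = [random_net(rng, f"c{i}") for i in range(3)]
        merged = merge_networks(nets)
        cells = shared_edge_decomposition(merged)
        assert sum(cells.values()) == merged.n_edges
        for edge in merged.edge_set():
            key = frozenset(
                f"c{i}" for i, n in enumerate(nets) if edge in n.edge_set()
            )
            assert cells[key] >= 1
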