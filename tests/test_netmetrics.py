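"""Network metrics and community structure against independent oracles.

The modularity oracle is the double-sum definition evaluated directly on
the adjacency matrix; the betweenness oracle enumerates all simple paths;
map-equation expectations are hand-evaluated closed forms.
"""

import math
import random
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from cadnet.netmetrics import (
    Partition,
    average_clustering,
    average_path_length,
    betweenness,
    degree_stats,
    louvain,
    map_equation,
    minimize_description_length,
    modularity,
    network_report,
    weak_components,
)

# hand evaluation of the two-level map equation on the bridge graph
# (two unit triangles joined by one edge, partitioned into the triangles):
# q = 2/14, H(Q) = 1 bit; each module: denom 8/14,
# H = 3/8*log2(8/3) + 2*(2/8)*2 + (1/8)*3  -> L = 1/7 + 2*(8/14)*H
BRIDGE_TRIANGLE_PARTITION_BITS = (
    2 / 14
    + 2 * (8 / 14) * (
        (3 / 8) * math.log2(8 / 3) + 2 * (2 / 8) * math.log2(8 / 2) + (1 / 8) * math.log2(8)
    )
)


def modularity_double_sum(g: nx.Graph, assignment: dict) -> float:
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes, key=str), weight="weight")
    k = a.sum(axis=1)
    two_w = a.sum()
    nodes = sorted(g.nodes, key=str)
    q = 0.0
    for i in range(len(nodes)):
        for j in range(len(nodes)):
            if assignment[nodes[i]] == assignment[nodes[j]]:
                q += a[i, j] - k[i] * k[j] / two_w
    return q / two_w


def betweenness_enumeration(g: nx.Graph) -> dict:
    """All-simple-path enumeration oracle (tiny graphs only)."""

    def simple_paths(s, t):
        out = []

        def walk(node, path):
            if node == t:
                out.append(list(path))
                return
            for nbr in g.neighbors(node):
                if nbr not in path:
                    path.append(nbr)
                    walk(nbr, path)
                    path.pop()

        walk(s, [s])
        return out

    score = {n: 0.0 for n in g.nodes}
    for s, t in combinations(g.nodes, 2):
        paths = simple_paths(s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        for p in shortest:
            for interior in p[1:-1]:
                score[interior] += 1.0 / len(shortest)
    return score


def random_weighted_graph(rng: random.Random, n: int) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, v in combinations(range(n), 2):
        if rng.random() < 0.45:
            g.add_edge(u, v, weight=rng.randint(1, 9))
    if g.number_of_edges() == 0:
        g.add_edge(0, 1, weight=1)
    return g


class TestDegreeStats:
    def test_triangle_avg_degree(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3)])
        avg, _, _, _ = degree_stats(g)
        assert avg == 2.0

    def test_star_avg_degree_closed_form(self):
        g = nx.star_graph(4)
        avg, _, _, _ = degree_stats(g)
        assert avg == pytest.approx(8 / 5)

    def test_weighted_degrees_match_hand_sums(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=3)
        g.add_edge("b", "c", weight=5)
        _, avg_w, _, strengths = degree_stats(g)
        assert strengths == {"a": 3, "b": 8, "c": 5}
        assert avg_w == pytest.approx(16 / 3)

    def test_isolates_count_toward_averages(self):
        g = nx.Graph([(1, 2)])
        g.add_node(3)
        avg, _, _, _ = degree_stats(g)
        assert avg == pytest.approx(2 / 3)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            degree_stats(nx.Graph())


class TestPathLength:
    def test_path_graph_closed_form(self):
        assert average_path_length(nx.path_graph(3)) == pytest.approx(4 / 3)

    def test_complete_graph_is_one(self):
        assert average_path_length(nx.complete_graph(5)) == 1.0

    def test_cross_component_pairs_excluded(self):
        g = nx.Graph([(1, 2), (3, 4)])
        assert average_path_length(g) == 1.0

    def test_no_connected_pair_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        with pytest.raises(ValueError):
            average_path_length(g)


class TestClustering:
    def test_triangle_fully_clustered(self):
        assert average_clustering(nx.complete_graph(3)) == 1.0

    def test_star_triangle_free(self):
        assert average_clustering(nx.star_graph(4)) == 0.0

    def test_triangle_plus_pendant(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (3, 4)])
        assert average_clustering(g) == pytest.approx((1 + 1 + 1 / 3 + 0) / 4)


class TestBetweenness:
    def test_path_center_single_mediated_pair(self):
        assert betweenness(nx.path_graph(3))[1] == 1.0

    def test_complete_graph_no_intermediaries(self):
        assert all(v == 0 for v in betweenness(nx.complete_graph(4)).values())

    def test_matches_enumeration_on_random_graphs(self):
        rng = random.Random(13)
        for _ in range(8):
            g = random_weighted_graph(rng, rng.randint(4, 6))
            expected = betweenness_enumeration(g)
            got = betweenness(g)
            for n in g.nodes:
                assert got[n] == pytest.approx(expected[n])

    def test_sum_equals_total_interior_path_length(self):
        # sum over nodes of betweenness = sum over connected pairs of
        # (shortest-path interior length), when shortest paths are unique —
        # in general the fractional counts still sum to (d(s,t)-1) per pair
        g = nx.path_graph(6)
        total = sum(betweenness(g).values())
        expected = sum(
            nx.shortest_path_length(g, s, t) - 1 for s, t in combinations(g, 2)
        )
        assert total == pytest.approx(expected)


class TestComponents:
    def test_connected_toy(self, bridge_graph):
        assert weak_components(bridge_graph) == 1

    def test_isolates_are_singleton_components(self):
        g = nx.Graph([(1, 2), (3, 4)])
        g.add_node(5)
        assert weak_components(g) == 3


class TestModularity:
    def test_single_community_is_zero(self, bridge_graph):
        part = Partition({n: 0 for n in bridge_graph})
        assert modularity(bridge_graph, part) == pytest.approx(0.0)

    def test_bridge_triangle_partition_value(self, bridge_graph):
        part = Partition({"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1})
        assert modularity(bridge_graph, part) == pytest.approx(5 / 14)

    def test_singleton_partition_on_triangle(self):
        g = nx.complete_graph(3)
        part = Partition({n: n for n in g})
        assert modularity(g, part) == pytest.approx(-1 / 3)

    def test_matches_double_sum_oracle_on_random_partitions(self):
        rng = random.Random(99)
        for _ in range(10):
            g = random_weighted_graph(rng, rng.randint(4, 8))
            for _ in range(10):
                assignment = {n: rng.randint(0, 3) for n in g.nodes}
                expected = modularity_double_sum(g, assignment)
                assert modularity(g, Partition(assignment)) == pytest.approx(expected)

    def test_matches_networkx_community_modularity(self, bridge_graph):
        part = Partition({"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1})
        expected = nx.community.modularity(
            bridge_graph, [{"a", "b", "c"}, {"d", "e", "f"}], weight="weight"
        )
        assert modularity(bridge_graph, part) == pytest.approx(expected)

    def test_uncovered_node_rejected(self, bridge_graph):
        with pytest.raises(ValueError):
            modularity(bridge_graph, Partition({"a": 0}))


class TestLouvain:
    def test_recovers_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        part, q = louvain(g, seed=0)
        assert part.n_communities == 2
        comms = part.communities()
        assert {frozenset(c) for c in comms} == {
            frozenset(range(5)), frozenset(range(5, 10)),
        }
        assert q == pytest.approx(0.5)

    def test_finds_brute_force_optimum_on_bridge(self, bridge_graph):
        part, q = louvain(bridge_graph, seed=1)
        assert q == pytest.approx(5 / 14)
        assert {frozenset(c) for c in part.communities()} == {
            frozenset({"a", "b", "c"}), frozenset({"d", "e", "f"}),
        }

    def test_deterministic_for_fixed_seed(self, bridge_graph):
        p1, q1 = louvain(bridge_graph, seed=7)
        p2, q2 = louvain(bridge_graph, seed=7)
        assert p1.assignment == p2.assignment and q1 == q2

    def test_returned_q_equals_recomputed_modularity(self):
        rng = random.Random(5)
        for _ in range(5):
            g = random_weighted_graph(rng, 8)
            part, q = louvain(g, seed=3)
            assert q == modularity(g, part)

    def test_q_at_least_singleton_partition(self):
        rng = random.Random(17)
        for _ in range(5):
            g = random_weighted_graph(rng, 8)
            part, q = louvain(g, seed=1)
            singleton = Partition({n: i for i, n in enumerate(g.nodes)})
            assert q >= modularity(g, singleton) - 1e-12

    def test_no_worse_than_networkx_louvain(self, bridge_graph):
        ours = louvain(bridge_graph, seed=0)[1]
        theirs = nx.community.modularity(
            bridge_graph,
            nx.community.louvain_communities(bridge_graph, weight="weight", seed=0),
            weight="weight",
        )
        assert ours >= theirs - 1e-9

    def test_edgeless_network_singleton_convention(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2, 3])
        part, q = louvain(g, seed=0)
        assert q == 0.0 and part.n_communities == 3


class TestMapEquation:
    def test_triangle_single_module_is_log2_three(self):
        g = nx.complete_graph(3)
        part = Partition({n: 0 for n in g})
        assert map_equation(g, part) == pytest.approx(math.log2(3))

    def test_single_module_equals_visit_rate_entropy(self):
        rng = random.Random(23)
        g = random_weighted_graph(rng, 7)
        part = Partition({n: 0 for n in g})
        strengths = dict(g.degree(weight="weight"))
        tot = sum(strengths.values())
        entropy = -sum(
            (s / tot) * math.log2(s / tot) for s in strengths.values() if s > 0
        )
        assert map_equation(g, part) == pytest.approx(entropy)

    def test_bridge_graph_hand_evaluated(self, bridge_graph):
        part = Partition({"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1})
        assert map_equation(bridge_graph, part) == pytest.approx(
            BRIDGE_TRIANGLE_PARTITION_BITS
        )

    def test_one_module_never_beats_optimum(self):
        rng = random.Random(31)
        for _ in range(5):
            g = random_weighted_graph(rng, 7)
            one = map_equation(g, Partition({n: 0 for n in g}))
            _, best = minimize_description_length(g, seed=2)
            assert best <= one + 1e-12


class TestMinimizeDescriptionLength:
    def test_two_cliques_with_weak_bridge_prefer_two_modules(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        nx.set_edge_attributes(g, 1, "weight")
        g.add_edge(0, 5, weight=1)
        part, bits = minimize_description_length(g, seed=0)
        assert part.n_communities == 2
        one_module = map_equation(g, Partition({n: 0 for n in g}))
        assert bits < one_module

    def test_single_edge_prefers_one_module(self):
        g = nx.Graph([(1, 2)])
        part, bits = minimize_description_length(g, seed=0)
        assert part.n_communities == 1
        assert bits == pytest.approx(1.0)  # two equal visit rates

    def test_deterministic_for_fixed_seed(self, bridge_graph):
        r1 = minimize_description_length(bridge_graph, seed=4)
        r2 = minimize_description_length(bridge_graph, seed=4)
        assert r1[0].assignment == r2[0].assignment and r1[1] == r2[1]

    def test_reported_bits_equal_recomputation(self, bridge_graph):
        part, bits = minimize_description_length(bridge_graph, seed=0)
        assert bits == map_equation(bridge_graph, part)


class TestNetworkReport:
    def test_fields_equal_individually_computed_metrics(self, bridge_graph):
        report = network_report(bridge_graph, seed=0)
        assert report.n_nodes == 6 and report.n_edges == 7
        assert report.avg_degree == pytest.approx(14 / 6)
        assert report.avg_weighted_degree == pytest.approx(14 / 6)
        assert report.density == pytest.approx(7 / 15)
        assert report.n_weak_components == 1
        assert report.avg_path_length == pytest.approx(average_path_length(bridge_graph))
        assert report.avg_clustering == pytest.approx(average_clustering(bridge_graph))
        assert report.modularity == pytest.approx(5 / 14)

    def test_hub_is_max_weighted_degree_alphabetical_ties(self, bridge_graph):
        # c and d tie at weighted degree 3; alphabetical tie-break → c
        assert network_report(bridge_graph, seed=0).hub == "c"

    def test_edgeless_network_degenerates_gracefully(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        report = network_report(g, seed=0)
        assert report.modularity == 0.0
        assert report.description_length == 0.0
        assert report.avg_path_length is None
        assert report.n_weak_components == 2

    def test_invariant_under_node_relabelling(self, bridge_graph):
        relabeled = nx.relabel_nodes(
            bridge_graph, {n: f"node_{n}" for n in bridge_graph}
        )
        a = network_report(bridge_graph, seed=0)
        b = network_report(relabeled, seed=0)
        for attr in ("avg_degree", "density", "avg_path_length", "avg_clustering",
                     "modularity", "description_length"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr))
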