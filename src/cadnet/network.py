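"""Weighted co-occurrence networks over cohort term sets.

An edge joins two terms whenever they appear together in at least one
hospitalization record; its weight is the number of records in which both
appear (each record contributes at most 1 per pair because terms are sets
within a record). Node frequency is the number of records containing the
term. Monopartite networks pair terms of one category; the bipartite
network pairs each diagnosis with each comorbidity within a record.

Bipartite node identifiers are ``(category, term)`` tuples so a term that
occurs in both vocabularies stays two distinct nodes; monopartite nodes
are plain term strings. Exports stringify tuple identifiers as
``"category:term"``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path

import networkx as nx

from .records import Category, Cohort

__all__ = [
    "CooccurrenceNetwork",
    "build_monopartite",
    "build_bipartite",
    "filter_edges",
    "write_edge_list",
    "write_node_list",
    "write_graphml",
    "write_gexf",
]

MODES = ("diagnosis", "comorbidity", "bipartite")


@dataclass(frozen=True)
class CooccurrenceNetwork:
    """A weighted undirected co-occurrence graph plus its construction mode."""

    mode: str
    graph: nx.Graph

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def total_weight(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def frequency(self, node) -> int:
        return self.graph.nodes[node]["frequency"]

    def term_of(self, node) -> str:
        return node[1] if isinstance(node, tuple) else node

    def validate(self) -> None:
        """Check construction invariants; raises AssertionError on violation."""
        for u, v, d in self.graph.edges(data=True):
            assert u != v, "self-loop"
            w = d["weight"]
            assert isinstance(w, int) and w >= 1, "weights are positive integers"
            assert w <= min(self.frequency(u), self.frequency(v)), (
                "edge weight exceeds endpoint frequency"
            )
            if self.mode == "bipartite":
                assert (
                    self.graph.nodes[u]["category"] != self.graph.nodes[v]["category"]
                ), "bipartite edge joins same-category nodes"
        for _, d in self.graph.nodes(data=True):
            assert d["frequency"] >= 1


def _add_nodes(g: nx.Graph, cohort: Cohort, category: Category, as_tuple: bool) -> None:
    for r in cohort:
        for term in r.terms(category):
            node = (category.value, term) if as_tuple else term
            if node in g:
                g.nodes[node]["frequency"] += 1
            else:
                g.add_node(node, category=category.value, frequency=1)


def _bump_edge(g: nx.Graph, u, v) -> None:
    if g.has_edge(u, v):
        g[u][v]["weight"] += 1
    else:
        g.add_edge(u, v, weight=1)


def build_monopartite(cohort: Cohort, category: Category | str) -> CooccurrenceNetwork:
    """Co-occurrence network over one term category.

    Every unordered pair of distinct terms of the category present in a
    record increments that pair's weight by 1. Terms appearing in any
    record become nodes even when they never co-occur (isolates kept).
    """
    category = Category(category)
    g = nx.Graph()
    _add_nodes(g, cohort, category, as_tuple=False)
    for r in cohort:
        for u, v in combinations(sorted(r.terms(category)), 2):
            _bump_edge(g, u, v)
    return CooccurrenceNetwork(mode=category.value, graph=g)


def build_bipartite(cohort: Cohort) -> CooccurrenceNetwork:
    """Diagnosis–comorbidity cross network.

    Every (diagnosis, comorbidity) pair present in a record increments the
    cross edge by 1, so the total edge weight equals
    sum over records of |diagnoses| * |comorbidities|.
    """
    g = nx.Graph()
    _add_nodes(g, cohort, Category.DIAGNOSIS, as_tuple=True)
    _add_nodes(g, cohort, Category.COMORBIDITY, as_tuple=True)
    for r in cohort:
        for dia, com in product(sorted(r.diagnoses), sorted(r.comorbidities)):
            _bump_edge(g, (Category.DIAGNOSIS.value, dia), (Category.COMORBIDITY.value, com))
    return CooccurrenceNetwork(mode="bipartite", graph=g)


def filter_edges(network: CooccurrenceNetwork, min_weight: int) -> CooccurrenceNetwork:
    """Keep edges with weight >= min_weight; keep ALL nodes.

    Nodes isolated by the filter persist (they count as singleton weakly
    connected components downstream); node frequencies are unchanged.
    """
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes(data=True))
    g.add_edges_from(
        (u, v, d)
        for u, v, d in network.graph.edges(data=True)
        if d["weight"] >= min_weight
    )
    return CooccurrenceNetwork(mode=network.mode, graph=g)


# ---------------------------------------------------------------------------
# export


def _as_string_graph(network: CooccurrenceNetwork) -> nx.Graph:
    mapping = {n: (f"{n[0]}:{n[1]}" if isinstance(n, tuple) else n) for n in network.graph}
    return nx.relabel_nodes(network.graph, mapping, copy=True)


def write_edge_list(network: CooccurrenceNetwork, path: str | Path) -> None:
    g = network.graph
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight", "type"])
        def ordered(u, v):
            if network.mode == "bipartite":  # diagnosis endpoint first
                return (u, v) if g.nodes[u]["category"] == "diagnosis" else (v, u)
            return (u, v) if network.term_of(u) <= network.term_of(v) else (v, u)

        rows = sorted(
            (network.term_of(a), network.term_of(b), d["weight"])
            for u, v, d in g.edges(data=True)
            for a, b in [ordered(u, v)]
        )
        for u, v, w in rows:
            writer.writerow([u, v, w, network.mode])


def write_node_list(network: CooccurrenceNetwork, path: str | Path) -> None:
    g = network.graph
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term", "category", "frequency"])
        rows = sorted(
            (network.term_of(n), d["category"], d["frequency"]) for n, d in g.nodes(data=True)
        )
        writer.writerows(rows)


def write_graphml(network: CooccurrenceNetwork, path: str | Path) -> None:
    nx.write_graphml(_as_string_graph(network), path)


def write_gexf(network: CooccurrenceNetwork, path: str | Path) -> None:
    nx.write_gexf(_as_string_graph(network), path)
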