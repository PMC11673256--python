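"""Topological metrics and community structure for co-occurrence networks.

Community structure is scored two ways:

* **Weighted Newman–Girvan modularity** ``Q = sum_c [W_c/W - (S_c/2W)^2]``
  with ``W`` the total edge weight, ``W_c`` the intra-community weight and
  ``S_c`` the community's weighted-degree sum, maximized by a Louvain-style
  two-phase (local move + aggregation) greedy optimizer implemented here.
* **Two-level map equation** ``L(M) = q H(Q) + sum_i p_i H(P^i)`` in bits,
  for an undirected weighted network without teleportation: node visit
  rates are the stationary distribution of the weighted random walk
  (weighted degree / 2W) and module exit probabilities are proportional to
  module boundary weight. Lower description length means the partition
  compresses the walk better.

Plain structural metrics (degree, clustering, betweenness, components,
path lengths) delegate to networkx; path lengths and betweenness are
unweighted ("number of steps"), with betweenness unnormalized, endpoints
excluded, and each unordered pair counted once.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .network import CooccurrenceNetwork

__all__ = [
    "Partition",
    "NetworkMetricsReport",
    "degree_stats",
    "average_path_length",
    "average_clustering",
    "betweenness",
    "weak_components",
    "modularity",
    "louvain",
    "map_equation",
    "minimize_description_length",
    "network_report",
]


def _graph(network) -> nx.Graph:
    return network.graph if isinstance(network, CooccurrenceNetwork) else network


def _term_of(network, node) -> str:
    if isinstance(network, CooccurrenceNetwork):
        return network.term_of(node)
    return node[1] if isinstance(node, tuple) else str(node)


@dataclass(frozen=True)
class Partition:
    """Node → community assignment with contiguous integer ids from 0."""

    assignment: Mapping

    def __post_init__(self):
        raw = dict(self.assignment)
        relabel: dict = {}
        normalized = {}
        for node in raw:  # insertion order fixes the id relabelling
            cid = raw[node]
            if cid not in relabel:
                relabel[cid] = len(relabel)
            normalized[node] = relabel[cid]
        object.__setattr__(self, "assignment", normalized)

    def __getitem__(self, node) -> int:
        return self.assignment[node]

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return [out[c] for c in sorted(out)]


def _check_cover(g: nx.Graph, partition: Partition) -> None:
    missing = [n for n in g.nodes if n not in partition.assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")


# ---------------------------------------------------------------------------
# structural metrics


def degree_stats(network):
    """(avg_degree, avg_weighted_degree, per-node degree dict, per-node strength dict).

    Averages run over ALL nodes, isolates included.
    """
    g = _graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = dict(g.degree())
    strengths = dict(g.degree(weight="weight"))
    n = g.number_of_nodes()
    return (
        sum(degrees.values()) / n,
        sum(strengths.values()) / n,
        degrees,
        strengths,
    )


def average_path_length(network) -> float:
    """Mean unweighted shortest-path length over connected unordered pairs.

    Pairs in different components are excluded; isolates contribute no
    pairs. Raises when no connected pair exists.
    """
    g = _graph(network)
    total = 0
    pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1
    if pairs == 0:
        raise ValueError("no connected pair of nodes")
    # each unordered pair counted twice above
    return total / pairs


def average_clustering(network) -> float:
    """Unweighted mean local clustering; degree<2 nodes contribute 0."""
    g = _graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return nx.average_clustering(g, count_zeros=True)


def betweenness(network) -> dict:
    """Unnormalized shortest-path betweenness, endpoints excluded."""
    g = _graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return nx.betweenness_centrality(g, normalized=False, weight=None)


def weak_components(network) -> int:
    """Connected-component count; isolates are singleton components."""
    return nx.number_connected_components(_graph(network))


# ---------------------------------------------------------------------------
# modularity and Louvain


def modularity(network, partition: Partition, resolution: float = 1.0) -> float:
    """Weighted Newman–Girvan modularity of a node partition."""
    g = _graph(network)
    _check_cover(g, partition)
    w_total = sum(d.get("weight", 1) for _, _, d in g.edges(data=True))
    if w_total == 0:
        return 0.0
    intra: dict[int, float] = {}
    strength: dict[int, float] = {}
    for u, v, d in g.edges(data=True):
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0.0) + d.get("weight", 1)
    for node, s in g.degree(weight="weight"):
        cid = partition[node]
        strength[cid] = strength.get(cid, 0.0) + s
    q = 0.0
    for cid in set(partition.assignment.values()):
        q += intra.get(cid, 0.0) / w_total - resolution * (
            strength.get(cid, 0.0) / (2.0 * w_total)
        ) ** 2
    return q


class _Aggregate:
    """Weighted graph state for one Louvain level (adjacency + self-loops)."""

    def __init__(self, g: nx.Graph, nodes: list):
        self.nodes = nodes
        self.adj: dict = {n: {} for n in nodes}
        self.selfw: dict = {n: 0.0 for n in nodes}
        for u, v, d in g.edges(data=True):
            w = d.get("weight", 1)
            if u == v:
                self.selfw[u] += w
            else:
                self.adj[u][v] = self.adj[u].get(v, 0.0) + w
                self.adj[v][u] = self.adj[v].get(u, 0.0) + w
        self.strength = {
            n: sum(self.adj[n].values()) + 2.0 * self.selfw[n] for n in nodes
        }
        self.w_total = (
            sum(w for nbrs in self.adj.values() for w in nbrs.values()) / 2.0
            + sum(self.selfw.values())
        )


def _louvain_level(agg: _Aggregate, rng: random.Random, resolution: float):
    """One local-move phase; returns (community dict, moved flag)."""
    comm = {n: i for i, n in enumerate(agg.nodes)}
    c_strength = {comm[n]: agg.strength[n] for n in agg.nodes}
    w = agg.w_total
    if w == 0:
        return comm, False
    order = list(agg.nodes)
    moved_any = False
    improved = True
    while improved:
        improved = False
        rng.shuffle(order)
        for node in order:
            old = comm[node]
            k = agg.strength[node]
            c_strength[old] -= k
            links: dict[int, float] = {}
            for nbr, wt in agg.adj[node].items():
                links[comm[nbr]] = links.get(comm[nbr], 0.0) + wt
            # value of joining community C relative to sitting alone (= 0)
            def join_value(cid: int) -> float:
                return links.get(cid, 0.0) / w - resolution * c_strength.get(
                    cid, 0.0
                ) * k / (2.0 * w * w)

            best_c, best_val = old, join_value(old)
            for cid in links:
                val = join_value(cid)
                if val > best_val + 1e-15:
                    best_c, best_val = cid, val
            if best_val < -1e-15:  # a fresh singleton community is better
                best_c = max(max(comm.values()), max(c_strength, default=0)) + 1
            comm[node] = best_c
            c_strength[best_c] = c_strength.get(best_c, 0.0) + k
            if best_c != old:
                improved = True
                moved_any = True
    return comm, moved_any


def louvain(network, resolution: float = 1.0, seed: int = 0):
    """Greedy two-phase modularity maximization.

    Deterministic for a given seed (node visit order is the seeded
    shuffle). Returns ``(Partition, Q)`` where Q is recomputed exactly via
    :func:`modularity` on the input network. An edgeless network yields the
    singleton partition with Q = 0 by convention.
    """
    g = _graph(network)
    nodes = sorted(g.nodes, key=str)
    if g.number_of_edges() == 0:
        part = Partition({n: i for i, n in enumerate(nodes)})
        return part, 0.0
    rng = random.Random(seed)
    # current mapping: original node -> supernode of the working graph
    mapping = {n: n for n in nodes}
    work = nx.Graph()
    work.add_nodes_from(nodes)
    work.add_edges_from((u, v, {"weight": d.get("weight", 1)}) for u, v, d in g.edges(data=True))
    while True:
        agg = _Aggregate(work, sorted(work.nodes, key=str))
        comm, moved = _louvain_level(agg, rng, resolution)
        if not moved:
            break
        mapping = {n: comm[mapping[n]] for n in nodes}
        new_work = nx.Graph()
        new_work.add_nodes_from(set(comm.values()))
        for u, v, d in work.edges(data=True):
            cu, cv = comm[u], comm[v]
            w = d.get("weight", 1)
            if new_work.has_edge(cu, cv):
                new_work[cu][cv]["weight"] += w
            else:
                new_work.add_edge(cu, cv, weight=w)
        for n, sw in agg.selfw.items():
            cu = comm[n]
            if sw:
                if new_work.has_edge(cu, cu):
                    new_work[cu][cu]["weight"] += sw
                else:
                    new_work.add_edge(cu, cu, weight=sw)
        work = new_work
    partition = Partition({n: mapping[n] for n in nodes})
    return partition, modularity(network, partition, resolution=resolution)


# ---------------------------------------------------------------------------
# map equation


def _plog(x: float) -> float:
    return -x * math.log2(x) if x > 0 else 0.0


def map_equation(network, partition: Partition) -> float:
    """Two-level map-equation description length in bits.

    Visit rates are weighted degrees normalized by 2W; module exit
    probability is the module's boundary weight over 2W. Isolated nodes
    have zero visit rate and contribute nothing; modules consisting only of
    isolates are skipped.
    """
    g = _graph(network)
    _check_cover(g, partition)
    for cid, members in enumerate(partition.communities()):
        if not members:
            raise ValueError(f"empty module {cid}")
    two_w = sum(d.get("weight", 1) for _, _, d in g.edges(data=True)) * 2.0
    if two_w == 0:
        return 0.0
    p = {n: s / two_w for n, s in g.degree(weight="weight")}
    exit_w: dict[int, float] = {}
    for u, v, d in g.edges(data=True):
        cu, cv = partition[u], partition[v]
        if cu != cv:
            w = d.get("weight", 1)
            exit_w[cu] = exit_w.get(cu, 0.0) + w
            exit_w[cv] = exit_w.get(cv, 0.0) + w
    q_i = {cid: w / two_w for cid, w in exit_w.items()}
    q = sum(q_i.values())
    length = 0.0
    if q > 0:
        length += q * sum(_plog(x / q) for x in q_i.values())
    for cid, members in enumerate(partition.communities()):
        denom = q_i.get(cid, 0.0) + sum(p[n] for n in members)
        if denom <= 0:
            continue  # module of isolates only
        h = _plog(q_i.get(cid, 0.0) / denom) if q_i.get(cid, 0.0) > 0 else 0.0
        h += sum(_plog(p[n] / denom) for n in members if p[n] > 0)
        length += denom * h
    return length


def minimize_description_length(network, seed: int = 0):
    """Greedy search for the partition minimizing the map equation.

    Seeded local moves from the singleton partition (each candidate move
    scored by full recomputation), followed by community-merge passes to
    escape single-node local minima. Deterministic for a given seed.
    Returns ``(Partition, bits)`` with bits recomputed exactly.
    """
    g = _graph(network)
    nodes = sorted(g.nodes, key=str)
    if g.number_of_edges() == 0:
        part = Partition({n: i for i, n in enumerate(nodes)})
        return part, 0.0
    rng = random.Random(seed)
    assignment = {n: i for i, n in enumerate(nodes)}
    best_l = map_equation(network, Partition(assignment))

    def try_assignment(cand: dict) -> float:
        return map_equation(network, Partition(cand))

    improved = True
    while improved:
        improved = False
        order = list(nodes)
        rng.shuffle(order)
        for node in order:  # node-level moves
            current = assignment[node]
            neighbor_comms = {assignment[nbr] for nbr in g.neighbors(node)}
            neighbor_comms.discard(current)
            for cid in sorted(neighbor_comms):
                cand = dict(assignment)
                cand[node] = cid
                l = try_assignment(cand)
                if l < best_l - 1e-12:
                    assignment, best_l = cand, l
                    improved = True
        # community-merge moves over connected community pairs
        comm_pairs = set()
        for u, v in g.edges():
            cu, cv = assignment[u], assignment[v]
            if cu != cv:
                comm_pairs.add((min(cu, cv), max(cu, cv)))
        for cu, cv in sorted(comm_pairs):
            cand = {n: (cu if c == cv else c) for n, c in assignment.items()}
            l = try_assignment(cand)
            if l < best_l - 1e-12:
                assignment, best_l = cand, l
                improved = True
    partition = Partition(assignment)
    return partition, map_equation(network, partition)


# ---------------------------------------------------------------------------
# composite report


@dataclass(frozen=True)
class NetworkMetricsReport:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_weighted_degree: float
    density: float
    n_weak_components: int
    avg_path_length: float | None
    avg_clustering: float
    modularity: float
    n_communities: int
    description_length: float
    n_modules: int
    hub: str | None
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "avg_weighted_degree": self.avg_weighted_degree,
            "density": self.density,
            "n_weak_components": self.n_weak_components,
            "avg_path_length": self.avg_path_length,
            "avg_clustering": self.avg_clustering,
            "modularity": self.modularity,
            "n_communities": self.n_communities,
            "description_length": self.description_length,
            "n_modules": self.n_modules,
            "hub": self.hub,
            "seed": self.seed,
        }
        return d


def network_report(network, seed: int = 0) -> NetworkMetricsReport:
    """All metrics for one network: the sensitivity-table row.

    The modularity column reports the Louvain-optimized Q; the
    description-length column reports the map-equation minimum found by
    :func:`minimize_description_length` (its own partition, not the
    modularity one). The hub is the node of maximal weighted degree, ties
    broken alphabetically by term.
    """
    g = _graph(network)
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return NetworkMetricsReport(0, 0, 0.0, 0.0, 0.0, 0, None, 0.0, 0.0, 0, 0.0, 0, None, seed)
    avg_deg, avg_wdeg, _, strengths = degree_stats(network)
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    try:
        apl = average_path_length(network)
    except ValueError:
        apl = None
    clustering = average_clustering(network)
    if m > 0:
        part_q, q = louvain(network, seed=seed)
        part_l, dl = minimize_description_length(network, seed=seed)
        n_comm, n_mod = part_q.n_communities, part_l.n_communities
    else:
        q, dl = 0.0, 0.0
        n_comm = n_mod = n
    hub = min(
        g.nodes,
        key=lambda node: (-strengths[node], _term_of(network, node)),
    )
    return NetworkMetricsReport(
        n_nodes=n,
        n_edges=m,
        avg_degree=avg_deg,
        avg_weighted_degree=avg_wdeg,
        density=density,
        n_weak_components=weak_components(network),
        avg_path_length=apl,
        avg_clustering=clustering,
        modularity=q,
        n_communities=n_comm,
        description_length=dl,
        n_modules=n_mod,
        hub=_term_of(network, hub),
        seed=seed,
    )
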