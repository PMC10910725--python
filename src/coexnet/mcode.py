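"""MCODE-style molecular complex detection.

Vertices are weighted by the core-clustering coefficient: the density of
the highest k-core of the closed neighbourhood, multiplied by that core's
level k.  Complexes grow outward from the highest-weighted unvisited seed,
admitting neighbours whose weight exceeds (1 - vwp) of the seed weight;
the haircut removes members left with within-cluster degree < 2.  Defaults
follow the published Cytoscape app (degree cutoff 2, node score cutoff
0.2, haircut on, fluff off).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = ["vertex_weights", "find_complexes", "Cluster", "ClusterSet"]


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(graph: nx.Graph, degree_cutoff: int = 2) -> dict:
    """Core-clustering-coefficient weight for every vertex.

    weight(v) = k_max(N[v]) * density(highest k-core of N[v]) over the
    closed neighbourhood N[v]; isolated vertices and vertices with degree
    below the cutoff score 0.
    """
    weights = {}
    for v in graph.nodes:
        if graph.degree(v) < max(degree_cutoff, 1):
            weights[v] = 0.0
            continue
        nbhd = graph.subgraph(set(graph.neighbors(v)) | {v})
        core = nx.core_number(nbhd)
        k_max = max(core.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        top_core = nbhd.subgraph([u for u, k in core.items() if k >= k_max])
        weights[v] = k_max * _density(top_core)
    return weights


@dataclass(frozen=True)
class Cluster:
    seed: object
    members: tuple
    density: float
    score: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """Clusters ordered by score (descending), node-disjoint."""

    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def __getitem__(self, i) -> Cluster:
        return self.clusters[i]


def _haircut(graph: nx.Graph, members: set) -> set:
    """Iteratively strip members with within-cluster degree < 2."""
    members = set(members)
    while True:
        sub = graph.subgraph(members)
        drop = {v for v in members if sub.degree(v) < 2}
        if not drop or drop == members:
            return members - drop if drop != members else set()
        members -= drop


def find_complexes(
    graph: nx.Graph,
    weights: dict | None = None,
    vwp: float = 0.2,
    degree_cutoff: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.1,
    max_depth: int = 100,
) -> ClusterSet:
    """Seeded complex expansion over a simple undirected graph.

    Seeds are processed in decreasing weight (ties by node ID); breadth-
    first expansion admits unvisited neighbours with weight strictly above
    (1 - vwp) * seed weight, to max_depth hops.  Optional fluff adds
    neighbours whose closed-neighbourhood density exceeds fluff_density
    (fluffed nodes may be shared between clusters).  Clusters score
    density x size and are returned sorted.
    """
    if not (0.0 <= vwp < 1.0):
        raise ValueError("vwp must lie in [0, 1)")
    if graph.number_of_nodes() == 0:
        return ClusterSet([])
    if weights is None:
        weights = vertex_weights(graph, degree_cutoff=degree_cutoff)
    order = sorted(graph.nodes, key=lambda v: (-weights.get(v, 0.0), str(v)))
    visited: set = set()
    clusters: list[Cluster] = []
    for seed in order:
        w_seed = weights.get(seed, 0.0)
        if seed in visited or w_seed <= 0.0 or graph.degree(seed) < degree_cutoff:
            continue
        cut = (1.0 - vwp) * w_seed
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for v in frontier:
                for u in graph.neighbors(v):
                    if u in members or u in visited:
                        continue
                    if weights.get(u, 0.0) > cut:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        if haircut:
            members = _haircut(graph, members)
        core_members = set(members)
        if fluff:
            for v in sorted(core_members, key=str):
                for u in graph.neighbors(v):
                    if u in members or u in visited:
                        continue
                    nbhd = graph.subgraph(set(graph.neighbors(u)) | {u})
                    if _density(nbhd) > fluff_density:
                        members.add(u)
        if len(members) < 2:
            continue
        visited |= core_members
        sub = graph.subgraph(members)
        dens = _density(sub)
        clusters.append(Cluster(
            seed=seed,
            members=tuple(sorted(members, key=str)),
            density=dens,
            score=dens * len(members),
        ))
    clusters.sort(key=lambda c: (-c.score, str(c.seed)))
    return ClusterSet(clusters)
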