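"""PPI graph construction, MCODE module detection and MCC hub ranking.

MCC (maximal clique centrality) of a node v is the sum of (|C| - 1)! over
all maximal cliques C containing v, computed by exact Bron-Kerbosch
enumeration (networkx ``find_cliques``); a node whose only maximal clique
is itself scores 0! = 1. MCODE follows the published three-stage procedure:
core-clustering vertex weighting, seeded greedy expansion with a vertex
weight percentage cutoff, and a haircut post-processing step. Module score
is density times size, with density = 2E / (n(n-1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from fflscope.io import PPIEdge


@dataclass(frozen=True)
class Module:
    nodes: frozenset[str]
    density: float
    score: float
    seed: str


@dataclass
class ModuleResult:
    modules: list[Module]


@dataclass
class HubRanking:
    """Nodes ordered by descending MCC score.

    Ties are broken by descending degree, then lexicographic node id, so
    repeated runs produce identical rankings.
    """

    scores: dict[str, float]
    order: list[str]
    top_k: int

    @property
    def top(self) -> list[str]:
        return self.order[: self.top_k]

    def rank_of(self, node: str) -> int:
        return self.order.index(node) + 1


def build_ppi(
    edges: list[PPIEdge],
    min_score: float = 0.4,
    restrict_to: set[str] | None = None,
) -> nx.Graph:
    """Graph of edges with confidence strictly > ``min_score``.

    With ``restrict_to`` given, both endpoints must belong to the set and
    every member appears as a node even if isolated after filtering.
    """
    g = nx.Graph()
    if restrict_to is not None:
        g.add_nodes_from(sorted(restrict_to))
    for e in edges:
        if e.node_a == e.node_b:
            continue
        if e.score <= min_score:
            continue
        if restrict_to is not None and (e.node_a not in restrict_to or e.node_b not in restrict_to):
            continue
        if g.has_edge(e.node_a, e.node_b):
            g[e.node_a][e.node_b]["score"] = max(g[e.node_a][e.node_b]["score"], e.score)
        else:
            g.add_edge(e.node_a, e.node_b, score=e.score)
    return g


def mcc_scores(graph: nx.Graph) -> dict[str, float]:
    """Exact MCC via maximal-clique enumeration."""
    scores = {v: 0.0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    # isolated nodes never appear in find_cliques output on some versions;
    # their only maximal clique is the singleton, worth 0! = 1
    for v, s in scores.items():
        if s == 0.0:
            scores[v] = 1.0
    return scores


def mcc_ranking(graph: nx.Graph, top_k: int = 15) -> HubRanking:
    if graph.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    scores = mcc_scores(graph)
    order = sorted(scores, key=lambda v: (-scores[v], -graph.degree(v), v))
    return HubRanking(scores=scores, order=order, top_k=top_k)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """MCODE stage 1: weight = k-core number x density of that k-core,
    both taken on the node's closed neighborhood."""
    weights: dict[str, float] = {}
    for v in graph.nodes:
        nbrs = set(graph.neighbors(v)) | {v}
        sub = graph.subgraph(nbrs)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core = nx.core_number(sub)
        k = max(core.values())
        kcore_nodes = [u for u, c in core.items() if c >= k]
        weights[v] = k * _density(sub.subgraph(kcore_nodes))
    return weights


def mcode_modules(
    graph: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    min_module_size: int = 3,
) -> ModuleResult:
    """MCODE module detection with the published plugin defaults.

    Stage 2 seeds at the highest-weight unassigned node and expands
    breadth-first over neighbors whose weight exceeds (1 - vwp) times the
    seed weight, never revisiting nodes already assigned to a module.
    Haircut iteratively strips singly-connected nodes. ``fluff`` is
    accepted for interface completeness but not implemented (the default
    keeps it off).
    """
    if fluff:
        raise NotImplementedError("fluff post-processing is not implemented")
    weights = _vertex_weights(graph)
    assigned: set[str] = set()
    modules: list[Module] = []
    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], v)):
        if seed in assigned or weights[seed] <= 0:
            continue
        cutoff = (1.0 - vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt: list[str] = []
            for u in frontier:
                for w in graph.neighbors(u):
                    if w in assigned or w in members:
                        continue
                    if weights[w] > cutoff:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
        if haircut:
            sub = graph.subgraph(members).copy()
            while True:
                leaves = [u for u in sub.nodes if sub.degree(u) < 2]
                if not leaves or sub.number_of_nodes() <= 2:
                    break
                sub.remove_nodes_from(leaves)
            members = set(sub.nodes)
        if len(members) < min_module_size:
            continue
        assigned |= members
        sub = graph.subgraph(members)
        dens = _density(sub)
        modules.append(Module(nodes=frozenset(members), density=dens,
                              score=dens * len(members), seed=seed))
    modules.sort(key=lambda m: (-m.score, -len(m.nodes), m.seed))
    return ModuleResult(modules=modules)
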