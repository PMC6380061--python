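"""Dense-module detection: a molecular-complex-detection (MCODE) style
algorithm on the co-expression network.

Vertices are weighted by the density of the highest k-core of their closed
neighborhood times that core's k; complexes are grown greedily from
high-weight seeds, including neighbors whose weight stays within
``node_score_cutoff`` of the seed weight.  Modules are made vertex-disjoint
(seeds and members are consumed), optionally trimmed to their 2-core
("haircut"), and filtered to a minimum size.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = ["Module", "score_vertices", "detect_modules"]


@dataclass(frozen=True)
class Module:
    """A dense cluster of genes detected in the co-expression network."""

    module_id: int
    genes: frozenset[str]
    mcode_score: float

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def sorted_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def _density(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def score_vertices(network: nx.Graph, k_core_param: int = 2) -> dict[str, float]:
    """MCODE vertex weights: highest-k-core number of the closed neighborhood
    times the density of that core.

    Nodes whose closed neighborhood holds no core of order ``k_core_param``
    or higher (isolated nodes, star centers, pendants) get weight 0.
    """
    weights: dict[str, float] = {}
    for v in network.nodes():
        nbrs = set(network[v])
        nbrs.add(v)
        if len(nbrs) < 3:
            weights[v] = 0.0
            continue
        H = network.subgraph(nbrs)
        core = nx.core_number(H)
        k_max = max(core.values())
        if k_max < k_core_param:
            weights[v] = 0.0
            continue
        core_nodes = [n for n, c in core.items() if c >= k_max]
        weights[v] = k_max * _density(H.subgraph(core_nodes))
    return weights


def _grow(network: nx.Graph, seed: str, weights: dict[str, float],
          threshold: float, used: set[str]) -> set[str]:
    """Greedy BFS expansion from a seed over unused, high-weight neighbors."""
    members = {seed}
    frontier = [seed]
    while frontier:
        node = frontier.pop()
        for nbr in network[node]:
            if nbr in members or nbr in used:
                continue
            if weights[nbr] >= threshold:
                members.add(nbr)
                frontier.append(nbr)
    return members


def _haircut(network: nx.Graph, members: set[str]) -> set[str]:
    """Trim to the 2-core of the induced subgraph (drop tree-like fringes)."""
    sub = network.subgraph(members).copy()
    sub.remove_edges_from(nx.selfloop_edges(sub))
    core = nx.k_core(sub, 2)
    return set(core.nodes())


def _fluff(network: nx.Graph, members: set[str], used: set[str],
           fluff_density: float) -> set[str]:
    """Add unused boundary neighbors whose closed neighborhood is dense."""
    extra: set[str] = set()
    for node in sorted(members):
        for nbr in network[node]:
            if nbr in members or nbr in used or nbr in extra:
                continue
            closed = set(network[nbr]) | {nbr}
            if _density(network.subgraph(closed)) > fluff_density:
                extra.add(nbr)
    return members | extra


def detect_modules(
    network: nx.Graph,
    node_score_cutoff: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    min_size: int = 5,
    k_core_param: int = 2,
    fluff_density: float = 0.5,
) -> list[Module]:
    """Detect dense, vertex-disjoint modules in a network.

    Seeds are taken in descending vertex weight (ties by node ID); each
    complex grows over neighbors with weight ≥ seed weight × (1 −
    ``node_score_cutoff``).  The optional fluff stage adds dense boundary
    neighbors; haircut then trims the complex to its 2-core.  Modules
    smaller than ``min_size`` are discarded.  Each module's ``mcode_score``
    is its induced density × node count; output is sorted by score
    descending, ties by smallest gene ID.
    """
    if network.number_of_nodes() == 0:
        return []
    weights = score_vertices(network, k_core_param=k_core_param)
    order = sorted(weights, key=lambda v: (-weights[v], v))
    used: set[str] = set()
    raw: list[set[str]] = []
    for seed in order:
        if seed in used or weights[seed] <= 0:
            continue
        members = _grow(network, seed, weights,
                        weights[seed] * (1.0 - node_score_cutoff), used)
        if fluff:
            members = _fluff(network, members, used, fluff_density)
        if haircut:
            members = _haircut(network, members)
        if members:
            used.update(members)
            if len(members) >= min_size:
                raw.append(members)

    scored = []
    for members in raw:
        sub = network.subgraph(members)
        scored.append((frozenset(members), _density(sub) * len(members)))
    scored.sort(key=lambda t: (-t[1], min(t[0])))
    return [Module(module_id=i + 1, genes=genes, mcode_score=score)
            for i, (genes, score) in enumerate(scored)]
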