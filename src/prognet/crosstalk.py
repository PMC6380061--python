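"""Module cross-talk network via permutation-tested inter-module edge counts.

Two modules cross-talk when the number of co-expression edges running
between them is larger than expected for random gene sets of the same
sizes.  The null distribution is built by repeatedly drawing two disjoint
uniform-random node sets from the network and counting the edges between
them; the p-value uses the permutation-inclusive (add-one) estimator so it
is never exactly zero.  Significant pairs (p < alpha) form the module
network; every module is kept as a node even when isolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np

from .mcode import Module

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationConfig",
    "count_cross_edges",
    "crosstalk_pvalue",
    "build_module_network",
]


@dataclass
class PermutationConfig:
    """Settings for the cross-talk permutation test."""

    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    fdr: bool = False  # optional Benjamini–Hochberg across module pairs

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def count_cross_edges(network: nx.Graph, genes_a, genes_b) -> int:
    """Number of network edges with one endpoint in each (disjoint) set."""
    a, b = set(genes_a), set(genes_b)
    if a & b:
        raise ValueError("gene sets must be disjoint")
    small, other = (a, b) if len(a) <= len(b) else (b, a)
    count = 0
    for u in small:
        if u in network:
            count += sum(1 for v in network[u] if v in other)
    return count


class _CrossEdgeCounter:
    """Dense boolean adjacency for fast repeated cross-edge counting."""

    def __init__(self, network: nx.Graph):
        self.nodes = list(network.nodes())
        self.index = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        adj = np.zeros((n, n), dtype=bool)
        for u, v in network.edges():
            i, j = self.index[u], self.index[v]
            adj[i, j] = adj[j, i] = True
        self.adj = adj
        self.n = n

    def count(self, idx_a: np.ndarray, idx_b: np.ndarray) -> int:
        return int(self.adj[np.ix_(idx_a, idx_b)].sum())

    def null_counts(self, size_a: int, size_b: int, n_perm: int,
                    rng: np.random.Generator) -> np.ndarray:
        """Cross-edge counts for n_perm draws of two disjoint random sets."""
        if size_a + size_b > self.n:
            raise ValueError("combined module size exceeds network node count")
        out = np.empty(n_perm, dtype=int)
        for i in range(n_perm):
            draw = rng.choice(self.n, size=size_a + size_b, replace=False)
            out[i] = self.count(draw[:size_a], draw[size_a:])
        return out


def _pvalue(null: np.ndarray, observed: int) -> float:
    return (1.0 + int((null >= observed).sum())) / (len(null) + 1.0)


def crosstalk_pvalue(
    network: nx.Graph,
    module_a: Module,
    module_b: Module,
    cfg: PermutationConfig,
    _counter: _CrossEdgeCounter | None = None,
    _rng: np.random.Generator | None = None,
) -> tuple[int, float]:
    """Observed cross-edge count and its permutation p-value.

    The null draws two disjoint uniform-random node sets of the modules'
    sizes from the whole network; p = (1 + #{null ≥ observed}) /
    (n_permutations + 1).
    """
    counter = _counter or _CrossEdgeCounter(network)
    rng = _rng or np.random.default_rng(cfg.seed)
    missing = (module_a.genes | module_b.genes) - set(counter.index)
    if missing:
        raise ValueError(f"module genes not in network: {sorted(missing)[:5]}")
    idx_a = np.array([counter.index[g] for g in module_a.sorted_genes])
    idx_b = np.array([counter.index[g] for g in module_b.sorted_genes])
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("modules must be disjoint")
    observed = counter.count(idx_a, idx_b)
    null = counter.null_counts(len(idx_a), len(idx_b), cfg.n_permutations, rng)
    return observed, _pvalue(null, observed)


def build_module_network(
    network: nx.Graph,
    modules: Sequence[Module],
    cfg: PermutationConfig,
) -> nx.Graph:
    """Permutation-test every module pair and keep significant cross-talks.

    Nodes are all module IDs (with ``size`` and ``mcode_score`` attributes),
    including modules with no significant cross-talk; edges carry
    ``cross_edge_count`` and ``p_value``.  With a fixed seed the result is
    reproducible bit for bit.
    """
    if len(modules) < 2:
        raise ValueError("need at least 2 modules")
    counter = _CrossEdgeCounter(network)
    rng = np.random.default_rng(cfg.seed)
    M = nx.Graph(alpha=float(cfg.alpha), n_permutations=int(cfg.n_permutations))
    for mod in modules:
        M.add_node(mod.module_id, size=mod.size, mcode_score=float(mod.mcode_score))
    results = []
    for a, b in combinations(modules, 2):
        obs, p = crosstalk_pvalue(network, a, b, cfg, _counter=counter, _rng=rng)
        results.append((a.module_id, b.module_id, obs, p))
    pvals = np.array([r[3] for r in results])
    if cfg.fdr:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, *_ = multipletests(pvals, alpha=cfg.alpha, method="fdr_bh")
        keep = reject
    else:
        p_adj = pvals
        keep = pvals < cfg.alpha
    for (ida, idb, obs, p), adj, kept in zip(results, p_adj, keep):
        if kept:
            M.add_edge(ida, idb, cross_edge_count=int(obs), p_value=float(p))
    mean_nbrs = 2.0 * M.number_of_edges() / M.number_of_nodes()
    M.graph["mean_neighbors"] = mean_nbrs
    logger.info(
        "module network: %d modules, %d significant cross-talks, mean neighbors %.3f",
        M.number_of_nodes(), M.number_of_edges(), mean_nbrs,
    )
    return M
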