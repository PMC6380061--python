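"""Rank-based gene co-expression network construction.

Every gene is linked to its k most correlated partners (Pearson), so the
graph adapts to pathway-specific correlation scales instead of applying one
global threshold.  The resulting union graph is simple and undirected: an
edge exists if either endpoint selected the other.  A selection count
(genes × k) and the deduplicated union edge count are both tracked because
they differ whenever two genes select each other.

Scale-free quality control fits log10(node count) against log10(degree) by
least squares, the conventional degree-distribution check for this kind of
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["pearson_matrix", "build_rank_network", "powerlaw_fit", "NetworkQC"]


def pearson_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Pearson correlation of gene expression profiles.

    Genes with zero variance across samples are dropped (Pearson is
    undefined for them) with a logged count.  Requires at least 3 samples.

    Returns
    -------
    DataFrame
        Symmetric gene × gene matrix with unit diagonal, values in [−1, 1].
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    values = expr.values
    sd = values.std(axis=1)
    keep = sd > 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d zero-variance genes before correlation", n_drop)
    values = values[keep]
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes with non-zero variance")
    corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


def build_rank_network(
    corr: pd.DataFrame, k: int = 10, ranking: str = "absolute"
) -> nx.Graph:
    """Build the top-k co-expression network from a correlation matrix.

    Each gene selects its ``k`` top-ranked partners (self excluded); the
    network is the undirected union of all selections.  Ranking is by
    ``|r|`` (default) or by signed ``r``; ties at the k-th rank are broken
    deterministically by lexicographic gene ID.

    Edge attributes: ``pearson_r`` and ``selected_by`` (which endpoint(s)
    placed the edge in their top-k).  Graph attributes record ``k``,
    ``selection_count`` (= genes × k) and the ranking mode.
    """
    genes = list(corr.index)
    n = len(genes)
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the gene count ({n})")
    stat = np.abs(corr.to_numpy()) if ranking == "absolute" else corr.to_numpy().copy()
    if ranking not in ("absolute", "signed"):
        raise ValueError("ranking must be 'absolute' or 'signed'")
    np.fill_diagonal(stat, -np.inf)
    # lexicographic rank of each gene ID, used as the deterministic tie-break
    lex_rank = np.empty(n, dtype=int)
    lex_rank[np.argsort(np.asarray(genes, dtype=object))] = np.arange(n)

    G = nx.Graph(k=int(k), ranking=ranking, selection_count=int(n * k))
    G.add_nodes_from(genes)
    r = corr.to_numpy()
    for i in range(n):
        top = np.lexsort((lex_rank, -stat[i]))[:k]
        gi = genes[i]
        for j in top:
            gj = genes[j]
            if G.has_edge(gi, gj):
                prev = G[gi][gj]["selected_by"]
                if gi not in prev.split(","):
                    G[gi][gj]["selected_by"] = "both"
            else:
                G.add_edge(gi, gj, pearson_r=float(r[i, j]), selected_by=gi)
    return G


@dataclass
class NetworkQC:
    """Summary statistics and scale-free fit of a co-expression network."""

    selection_count: int
    union_edge_count: int
    mean_neighbors: float
    powerlaw_applicable: bool
    powerlaw_correlation: float
    powerlaw_r2: float
    powerlaw_slope: float

    def to_dict(self) -> dict:
        return asdict(self)


def powerlaw_fit(network: nx.Graph) -> NetworkQC:
    """Degree-distribution power-law fit of a network.

    Least-squares fit of log10(number of nodes with degree d) versus
    log10(d) over observed degrees d ≥ 1.  ``powerlaw_r2`` is the R² of the
    log–log fit; ``powerlaw_correlation`` is the Pearson correlation between
    the observed counts and the fitted power law on the original scale (the
    convention used by common network-analyzer tools).  With fewer than 3
    distinct degrees the fit is marked not applicable.
    """
    n_nodes = network.number_of_nodes()
    if n_nodes == 0:
        raise ValueError("empty network")
    degrees = np.array([d for _, d in network.degree()], dtype=int)
    n_edges = network.number_of_edges()
    selection_count = int(network.graph.get("selection_count", 0))
    mean_neighbors = 2.0 * n_edges / n_nodes

    vals, counts = np.unique(degrees[degrees > 0], return_counts=True)
    if len(vals) < 3:
        return NetworkQC(selection_count, n_edges, mean_neighbors,
                         False, float("nan"), float("nan"), float("nan"))
    x = np.log10(vals.astype(float))
    y = np.log10(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted_log = slope * x + intercept
    ss_res = float(np.sum((y - fitted_log) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    fitted = 10.0 ** fitted_log
    with np.errstate(invalid="ignore"):
        corr = abs(float(np.corrcoef(counts.astype(float), fitted)[0, 1]))
    return NetworkQC(selection_count, n_edges, mean_neighbors,
                     True, corr, r2, float(slope))
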