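"""GeneRank prioritization of modules over the cross-talk network.

GeneRank is PageRank with a prior: a module's importance r_j blends its own
resampling-derived prior p_j with importance flowing in from its network
neighbors, weighted by a damping constant d,

    r_j = (1 - d) p_j + d * sum_i w_ij r_i / degree_i,

whose fixed point solves the linear system (I - d W^T D^{-1}) r = (1 - d) p.
The direct sparse/dense solve is the default; the Jacobi iteration is kept
as a cross-check because the fixed-point form above *is* Jacobi on that
system.  Isolated modules receive and give nothing: the degree division is
defined 0-safe and their importance is (1 - d) p_j.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .prognostic import PrognosticProfile

__all__ = [
    "GeneRankResult",
    "generank_solve",
    "generank_network",
    "select_top",
    "select_control",
    "round_half_up",
]


@dataclass
class GeneRankResult:
    """Importance scores and ranking of modules."""

    module_ids: tuple[int, ...]
    scores: np.ndarray  # aligned with module_ids
    ranking: tuple[int, ...]  # module IDs sorted by importance, best first
    damping: float

    def score_of(self, module_id: int) -> float:
        return float(self.scores[self.module_ids.index(module_id)])


def _validate(W: np.ndarray, p: np.ndarray, d: float) -> None:
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.array_equal(W, W.T):
        raise ValueError("W must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("W must have a zero diagonal")
    if len(p) != W.shape[0]:
        raise ValueError("prior length must match W")
    if np.any(np.asarray(p) < 0):
        raise ValueError("prior must be non-negative")
    if not 0 <= d < 1:
        raise ValueError("damping d must be in [0, 1)")


def generank_solve(
    W: np.ndarray,
    priors: np.ndarray,
    d: float = 0.70,
    method: str = "direct",
    tol: float = 1e-10,
    max_iter: int = 10000,
    module_ids: Sequence[int] | None = None,
    tie_break: Sequence[float] | None = None,
) -> GeneRankResult:
    """Solve the GeneRank system for a symmetric 0/1 adjacency ``W``.

    ``method='direct'`` solves the linear system; ``method='jacobi'``
    iterates the fixed-point form until max |Δr| < tol (raising if it does
    not converge within ``max_iter``).  Ranking ties are broken by higher
    prior (or the explicit ``tie_break`` vector), then by module ID.
    """
    W = np.asarray(W, dtype=float)
    p = np.asarray(priors, dtype=float)
    _validate(W, p, d)
    n = W.shape[0]
    ids = tuple(module_ids) if module_ids is not None else tuple(range(1, n + 1))
    deg = W.sum(axis=1)
    inv_deg = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    # column j of A holds d * w_ij / degree_i over i: A = d * (W / deg_i) ^ T
    A = d * (W * inv_deg[:, None]).T
    if method == "direct":
        r = np.linalg.solve(np.eye(n) - A, (1.0 - d) * p)
    elif method == "jacobi":
        r = p.copy()
        for _ in range(max_iter):
            r_new = (1.0 - d) * p + A @ r
            delta = np.max(np.abs(r_new - r)) if n else 0.0
            r = r_new
            if delta < tol:
                break
        else:
            raise RuntimeError(
                "Jacobi iteration did not converge; use method='direct'"
            )
    else:
        raise ValueError("method must be 'direct' or 'jacobi'")
    tb = np.asarray(tie_break, dtype=float) if tie_break is not None else p
    order = sorted(range(n), key=lambda i: (-r[i], -tb[i], ids[i]))
    return GeneRankResult(
        module_ids=ids,
        scores=r,
        ranking=tuple(ids[i] for i in order),
        damping=d,
    )


def generank_network(
    module_network: nx.Graph,
    profiles: Sequence[PrognosticProfile],
    d: float = 0.70,
    method: str = "direct",
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> GeneRankResult:
    """GeneRank over a module network with resampling priors.

    The prior of module j is its significance frequency divided by the
    number of resamples (initial_importance ∈ [0, 1]).
    """
    prof_by_id = {p.module_id: p for p in profiles}
    ids = sorted(module_network.nodes())
    missing = [i for i in ids if i not in prof_by_id]
    if missing:
        raise ValueError(f"no prognostic profile for modules {missing[:5]}")
    W = nx.to_numpy_array(module_network, nodelist=ids, weight=None)
    priors = np.array([prof_by_id[i].initial_importance for i in ids])
    return generank_solve(W, priors, d=d, method=method, tol=tol,
                          max_iter=max_iter, module_ids=ids)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves rounded up (12.5 → 13)."""
    return int(np.floor(x + 0.5))


def select_top(
    result: GeneRankResult,
    fraction: float = 0.05,
    module_count: int | None = None,
    n_select: int | None = None,
) -> tuple[int, ...]:
    """Top-fraction module IDs by GeneRank importance.

    The selection size is round-half-up(fraction × module count), at least
    1; ``n_select`` overrides the fraction when an explicit count is wanted.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    total = module_count if module_count is not None else len(result.module_ids)
    count = n_select if n_select is not None else max(1, round_half_up(fraction * total))
    return result.ranking[:count]


def select_control(
    profiles: Sequence[PrognosticProfile], count: int
) -> tuple[int, ...]:
    """Baseline selection: the ``count`` modules with the highest
    significance frequency, ignoring the module network (ties by larger
    |mean coefficient|, then module ID)."""
    if count <= 0:
        raise ValueError("count must be positive")
    if count > len(profiles):
        raise ValueError("count exceeds number of profiles")

    def key(p: PrognosticProfile):
        coef = abs(p.mean_coefficient) if np.isfinite(p.mean_coefficient) else -np.inf
        return (-p.sig_frequency, -coef, p.module_id)

    ranked = sorted(profiles, key=key)
    return tuple(p.module_id for p in ranked[:count])
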