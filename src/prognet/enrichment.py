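"""Hypergeometric over-representation of selected-module genes in
annotation lists (known cancer genes, drug targets, gene-age classes, ...).

The p-value is the upper tail of the hypergeometric distribution: the
probability of drawing at least x annotated genes when K genes are sampled
from a universe of M containing N annotated ones.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["EnrichmentResult", "hypergeom_test", "load_gene_list", "enrich_many"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One over-representation test of a query set against an annotation."""

    x: int  # overlap count
    M: int  # universe size
    K: int  # query size
    N: int  # annotation size (within the universe)
    p_value: float

    def as_row(self) -> dict:
        return {"x": self.x, "M": self.M, "K": self.K, "N": self.N,
                "p_value": self.p_value}


def hypergeom_test(
    query: Iterable[str],
    annotation: Iterable[str],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Upper-tail hypergeometric test P(overlap ≥ x).

    The annotation is intersected with the universe before testing; the
    query must be a subset of the universe.
    """
    u = set(universe)
    q = set(query)
    if not u:
        raise ValueError("universe is empty")
    if not q:
        raise ValueError("query is empty")
    if not q <= u:
        raise ValueError("query genes must be contained in the universe")
    a = set(annotation) & u
    x = len(q & a)
    M, K, N = len(u), len(q), len(a)
    # population M, N annotated "successes", K draws; P(X >= x)
    p = float(hypergeom(M, N, K).sf(x - 1))
    p = min(max(p, 0.0), 1.0)
    if p == 0.0:
        p = float(hypergeom(M, N, K).pmf(min(K, N)))  # guard against underflow
    return EnrichmentResult(x=x, M=M, K=K, N=N, p_value=p)


def load_gene_list(path: str | os.PathLike) -> set[str]:
    """One gene ID per line; blank lines and '#' comments ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def enrich_many(
    query: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Run :func:`hypergeom_test` for every named annotation list."""
    u = set(universe)
    q = set(query)
    rows = []
    for name, ann in annotations.items():
        res = hypergeom_test(q, ann, u)
        rows.append({"list": name, **res.as_row()})
    return pd.DataFrame(rows).set_index("list")
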