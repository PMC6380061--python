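"""Readers, writers and validated containers for expression and clinical data.

Expression matrices are genes × samples tables (first column gene/probe IDs,
header row sample IDs).  Clinical tables carry one row per sample with a
follow-up time and an event indicator (1 = death observed, 0 = censored).
Graphs (co-expression networks, module networks) are exchanged as GraphML,
GML or plain two-column edge lists so that any standard graph tool can read
them.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "load_probe_map",
    "load_expression",
    "load_clinical",
    "export_graph",
    "read_graph",
    "align_samples",
]


def _sep_for(path: str | os.PathLike) -> str:
    """Delimiter inferred from the file extension (.csv → comma, else tab)."""
    return "," if str(path).lower().endswith(".csv") else "\t"


class ExpressionMatrix:
    """A genes × samples expression matrix with unique row/column labels.

    Rows containing any missing value are dropped (and counted in the log):
    downstream correlation and Cox computations assume a complete matrix.

    Parameters
    ----------
    data
        DataFrame indexed by gene ID with sample IDs as columns.  Values must
        be numeric; the units are arbitrary but must be consistent (the
        matrix is assumed pre-normalized).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene IDs: {dups} ...")
        if data.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TypeError("expression values must be numeric")
        n_missing = int(data.isna().any(axis=1).sum())
        if n_missing:
            logger.info("dropping %d gene rows with missing values", n_missing)
            data = data.dropna(axis=0, how="any")
        if data.shape[1] < 2:
            raise ValueError("expression matrix needs at least 2 samples")
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "gene"
        self.data.columns = self.data.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def to_file(self, path: str | os.PathLike) -> None:
        self.data.to_csv(path, sep=_sep_for(path), index_label="gene")

    def __repr__(self) -> str:  # pragma: no cover
        g, s = self.shape
        return f"<ExpressionMatrix {g} genes x {s} samples>"


class ClinicalTable:
    """Per-sample survival information: follow-up time and event status."""

    def __init__(self, data: pd.DataFrame):
        required = {"time", "event"}
        if not required.issubset(data.columns):
            raise ValueError("clinical table needs columns: sample, time, event")
        if data.index.duplicated().any():
            raise ValueError("duplicate sample IDs in clinical table")
        time = pd.to_numeric(data["time"], errors="raise")
        if (time < 0).any():
            raise ValueError("negative survival time")
        event = pd.to_numeric(data["event"], errors="raise")
        if not event.isin([0, 1]).all():
            bad = sorted(event[~event.isin([0, 1])].unique())
            raise ValueError(f"event status must be 0 or 1, got {bad}")
        out = pd.DataFrame(
            {"time": time.astype(float), "event": event.astype(int)},
            index=data.index.astype(str),
        )
        out.index.name = "sample"
        self.data = out

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)])

    def to_file(self, path: str | os.PathLike) -> None:
        self.data.to_csv(path, sep=_sep_for(path), index_label="sample")

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ClinicalTable {len(self)} samples, {int(self.event.sum())} events>"


def load_probe_map(path: str | os.PathLike) -> dict[str, str]:
    """Load a two-column probe → gene map (header optional: probe, gene)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if list(df.columns[:2]) != ["probe", "gene"]:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str, header=None,
                         names=["probe", "gene"])
    if df["probe"].duplicated().any():
        raise ValueError("a probe maps to more than one gene")
    return dict(zip(df["probe"], df["gene"]))


def load_expression(
    path: str | os.PathLike,
    probe_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Load an expression matrix, optionally collapsing probes to genes.

    With a probe map, probe rows mapping to the same gene are replaced by
    their per-sample arithmetic mean (the conventional probe-averaging step);
    probes absent from the map are dropped with a logged count.  Without a
    map, duplicate gene IDs are an error.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value at gene {raw.index[row]!r}, "
            f"sample {raw.columns[col]!r}: {raw.iat[row, col]!r}"
        )
    if probe_map is not None:
        known = numeric.index.isin(probe_map.keys())
        n_unknown = int((~known).sum())
        if n_unknown:
            logger.info("dropping %d probes absent from the probe map", n_unknown)
        numeric = numeric.loc[known]
        genes = numeric.index.map(lambda p: probe_map[p])
        numeric = numeric.groupby(genes, sort=True).mean()
    return ExpressionMatrix(numeric)


def load_clinical(path: str | os.PathLike) -> ClinicalTable:
    """Load a clinical table with columns sample, time, event."""
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = {c.lower(): c for c in df.columns}
    for name in ("sample", "time", "event"):
        if name not in cols:
            raise ValueError(f"clinical table is missing column {name!r}")
    df = df.rename(columns={cols[k]: k for k in ("sample", "time", "event")})
    df["sample"] = df["sample"].astype(str)
    return ClinicalTable(df.set_index("sample"))


def align_samples(
    expr: ExpressionMatrix, clinical: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both tables to their shared samples (matrix column order)."""
    shared = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    n_drop = (len(expr.sample_ids) - len(shared), len(clinical) - len(shared))
    if any(n_drop):
        logger.info(
            "sample alignment: dropping %d matrix / %d clinical samples", *n_drop
        )
    if not shared:
        raise ValueError("expression matrix and clinical table share no samples")
    return expr.subset_samples(shared), clinical.subset(shared)


_GRAPH_FORMATS = ("graphml", "gml", "edgelist")


def _sanitize(G: nx.Graph) -> nx.Graph:
    """Copy with attribute values coerced to GraphML/GML-safe scalars."""
    H = nx.Graph()
    H.graph.update({k: _scalar(v) for k, v in G.graph.items()})
    for n, attrs in G.nodes(data=True):
        H.add_node(n, **{k: _scalar(v) for k, v in attrs.items()})
    for u, v, attrs in G.edges(data=True):
        H.add_edge(u, v, **{k: _scalar(val) for k, val in attrs.items()})
    return H


def _scalar(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer)):
        return int(v)
    if isinstance(v, (float, np.floating)):
        return float(v)
    if isinstance(v, str):
        return v
    if isinstance(v, (set, frozenset, list, tuple)):
        return ",".join(str(x) for x in sorted(v))
    return str(v)


def export_graph(
    network: nx.Graph, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a network as GraphML, GML or a two-column edge list.

    Node and edge attributes (correlation, p-values, module membership) are
    preserved for GraphML/GML; the edge list keeps topology only.
    """
    if format is None:
        ext = str(path).rsplit(".", 1)[-1].lower()
        format = {"graphml": "graphml", "gml": "gml", "txt": "edgelist",
                  "tsv": "edgelist", "edgelist": "edgelist"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer graph format from {path!r}")
    if format not in _GRAPH_FORMATS:
        raise ValueError(f"unsupported graph format {format!r}; use one of {_GRAPH_FORMATS}")
    G = _sanitize(network)
    if format == "graphml":
        nx.write_graphml(G, path)
    elif format == "gml":
        nx.write_gml(G, str(path), stringizer=str)
    else:
        with open(path, "w") as fh:
            for u, v in G.edges():
                fh.write(f"{u}\t{v}\n")


def read_graph(path: str | os.PathLike, format: str | None = None) -> nx.Graph:
    """Read back a graph written by :func:`export_graph`."""
    if format is None:
        ext = str(path).rsplit(".", 1)[-1].lower()
        format = {"graphml": "graphml", "gml": "gml"}.get(ext, "edgelist")
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "gml":
        return nx.read_gml(str(path))
    with open(path) as fh:
        G = nx.Graph()
        for line in fh:
            if line.strip():
                u, v = line.split()[:2]
                G.add_edge(u, v)
        return G
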