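"""Signed metabolite co-accumulation network: construction, counts, export.

Nodes are traits; an edge joins every unordered pair whose Spearman rho
passes the magnitude threshold, labelled by sign.  Export is Cytoscape-ready:
a SIF edge file (interaction token ``pos``/``neg``), tab-delimited node and
edge attribute tables, and a positive-edges-only SIF variant for layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import MissingLabelError, ShapeError
from .correlation import CorrelationMatrix

EDGE_COLUMNS = ["a", "b", "rho", "sign"]


@dataclass
class SignedEdgeList:
    """Canonically ordered (a < b) signed edges with optional node attributes."""

    edges: pd.DataFrame  # columns a, b, rho, sign
    threshold: float
    inclusive: bool = True
    node_attrs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if list(self.edges.columns) != EDGE_COLUMNS:
            self.edges = self.edges[EDGE_COLUMNS]

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["a"]) | set(self.edges["b"]))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.a, row.b, rho=row.rho, sign=row.sign)
        return g


def build_network(
    corr: CorrelationMatrix, threshold: float = 0.3, inclusive: bool = True
) -> SignedEdgeList:
    """One signed edge per unordered trait pair with |rho| passing the threshold.

    Undefined (NaN) pairs never form edges.  Edge order is deterministic:
    lexicographic in (a, b) with a < b.
    """
    rho = corr.rho
    if rho.shape[0] != rho.shape[1] or not rho.index.equals(rho.columns):
        raise ShapeError("expected a square symmetric correlation matrix")
    ids = [str(i) for i in rho.index]
    mat = rho.to_numpy(dtype=float)
    records = []
    order = np.argsort(ids)
    for pos_i, i in enumerate(order):
        for j in order[pos_i + 1 :]:
            r = mat[i, j]
            if np.isnan(r):
                continue
            passes = abs(r) >= threshold if inclusive else abs(r) > threshold
            if passes:
                records.append(
                    (ids[i], ids[j], float(r), "+" if r > 0 else "-")
                )
    edges = pd.DataFrame(records, columns=EDGE_COLUMNS)
    return SignedEdgeList(edges=edges, threshold=threshold, inclusive=inclusive)


def edge_counts(net: SignedEdgeList) -> tuple[int, int]:
    """(number of positive edges, number of negative edges)."""
    n_pos = int((net.edges["sign"] == "+").sum())
    n_neg = int((net.edges["sign"] == "-").sum())
    return n_pos, n_neg


def intra_cluster_fraction(
    net: SignedEdgeList, clusters: pd.Series, sign: str
) -> float:
    """Fraction of edges of the given sign whose endpoints share a cluster label.

    Returns NaN when the network has no edge of that sign (0/0 undefined).
    """
    sub = net.edges.loc[net.edges["sign"] == sign]
    if sub.empty:
        return float("nan")
    missing = (set(sub["a"]) | set(sub["b"])) - set(clusters.index.astype(str))
    if missing:
        raise MissingLabelError(f"nodes without cluster label: {sorted(missing)}")
    labels = clusters.astype(str)
    same = labels.loc[sub["a"]].to_numpy() == labels.loc[sub["b"]].to_numpy()
    return float(same.mean())


def export_network(net: SignedEdgeList, outdir: str | Path) -> dict[str, Path]:
    """Write SIF + attribute tables; returns the paths written.

    Files: ``network.sif`` (all edges), ``network_positive.sif`` (layout
    variant), ``edge_attributes.tsv`` (a, b, rho, sign), and
    ``node_attributes.tsv`` when node attributes are present.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    token = {"+": "pos", "-": "neg"}
    paths: dict[str, Path] = {}

    def _write_sif(path: Path, edges: pd.DataFrame) -> None:
        with open(path, "w") as fh:
            for row in edges.itertuples(index=False):
                fh.write(f"{row.a}\t{token[row.sign]}\t{row.b}\n")

    paths["sif"] = outdir / "network.sif"
    _write_sif(paths["sif"], net.edges)
    paths["sif_positive"] = outdir / "network_positive.sif"
    _write_sif(paths["sif_positive"], net.edges.loc[net.edges["sign"] == "+"])
    paths["edge_attrs"] = outdir / "edge_attributes.tsv"
    net.edges.to_csv(paths["edge_attrs"], sep="\t", index=False, lineterminator="\n")
    if not net.node_attrs.empty:
        paths["node_attrs"] = outdir / "node_attributes.tsv"
        net.node_attrs.to_csv(
            paths["node_attrs"], sep="\t", index_label="node", lineterminator="\n"
        )
    return paths


def read_network(edge_attrs_path: str | Path, threshold: float = 0.3) -> SignedEdgeList:
    """Reconstruct a SignedEdgeList from an exported edge attribute table."""
    edges = pd.read_csv(edge_attrs_path, sep="\t", dtype={"a": str, "b": str})
    return SignedEdgeList(edges=edges, threshold=threshold)
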