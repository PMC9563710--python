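"""Target filtering, over-representation analysis, and the anti-correlation network.

Predicted miRNA targets are gated on an inclusive aggregate-score
threshold (>= 50) and intersected with the expressed mRNA set.  Gene-set
over-representation uses the one-sided upper-tail hypergeometric test
with Benjamini-Hochberg FDR control.  The regulatory network keeps a
(miRNA, gene) candidate pair as an edge when the Pearson correlation of
their expression profiles across the shared samples is -0.9 or lower
(inclusive bound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .config import log
from .diffexpr import bh_adjust

__all__ = [
    "GeneSet",
    "Edge",
    "read_gmt",
    "filter_targets",
    "hypergeom_pvalue",
    "hypergeom_enrich",
    "correlation_edges",
    "export_network",
]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id} has no members")


@dataclass(frozen=True)
class Edge:
    mirna_id: str
    gene_id: str
    r: float


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a tab-delimited GMT file."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets.append(GeneSet(parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def filter_targets(
    targets: pd.DataFrame, expressed: set[str], min_score: float = 50.0
) -> pd.DataFrame:
    """Keep target rows with aggregate_score >= min_score (inclusive) and
    gene_id in the expressed mRNA set.  Idempotent."""
    if targets.duplicated(["mirna_id", "gene_id"]).any():
        raise ValueError("(mirna_id, gene_id) pairs must be unique")
    kept = targets[
        (targets["aggregate_score"] >= min_score)
        & targets["gene_id"].isin(expressed)
    ].reset_index(drop=True)
    log.info(
        "filter_targets: %d/%d rows kept, %d unique genes",
        len(kept), len(targets), kept["gene_id"].nunique(),
    )
    return kept


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail over-representation p-value P(X >= k),
    X ~ Hypergeometric(N, K, n).  k = 0 gives p = 1."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError("require 0 <= k <= min(K, n) and K, n <= N")
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def hypergeom_enrich(
    query: set[str],
    sets: list[GeneSet],
    background: set[str],
    q_max: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of gene sets in a query.

    For a background of N genes containing K members of a set, a query of
    n genes with k hits has p = P(X >= k), X ~ Hypergeometric(N, K, n).
    Sets with no background member are skipped; q is BH across tested
    sets and rows with q < q_max are flagged significant.
    """
    outside = query - background
    if outside:
        raise ValueError(f"query genes outside background: {sorted(outside)[:5]}")
    N, n = len(background), len(query)
    rows = []
    for s in sets:
        members = s.members & background
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        rows.append(
            {"set_id": s.set_id, "description": s.description,
             "k": k, "K": K, "n": n, "N": N,
             "p": hypergeom_pvalue(k, N, K, n)}
        )
    out = pd.DataFrame(
        rows, columns=["set_id", "description", "k", "K", "n", "N", "p"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < q_max
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def correlation_edges(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    candidate_pairs,
    r_max: float = -0.9,
) -> list[Edge]:
    """Anti-correlation edges among candidate (miRNA, gene) pairs.

    Pearson r is computed across the shared ordered sample set (>= 3
    samples required); an edge is retained iff r <= r_max (inclusive at
    the -0.9 default).  Pairs where either profile is constant have no
    defined correlation and are skipped with a warning.
    """
    if list(mirna_expr.columns) != list(mrna_expr.columns):
        raise ValueError("miRNA and mRNA matrices must share the same ordered samples")
    if mirna_expr.shape[1] < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    edges: list[Edge] = []
    n_skipped = 0
    for mirna_id, gene_id in candidate_pairs:
        if mirna_id not in mirna_expr.index or gene_id not in mrna_expr.index:
            continue
        x = mirna_expr.loc[mirna_id].to_numpy(dtype=float)
        y = mrna_expr.loc[gene_id].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_skipped += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r <= r_max:
            edges.append(Edge(mirna_id, gene_id, r))
    if n_skipped:
        log.warning("correlation_edges: %d constant-profile pairs skipped", n_skipped)
    log.info("correlation_edges: %d edges retained at r <= %g", len(edges), r_max)
    return edges


def export_network(
    edges: list[Edge],
    mode_table: pd.DataFrame | None,
    sif_path,
    attrs_path,
    graphml_path=None,
) -> None:
    """Write the network as a SIF edge list plus a node-attribute table.

    Node attributes carry the node type (miRNA / gene) and, for miRNAs,
    the merged inheritance mode; miRNAs absent from the mode table are
    labelled ``unclassified``.  A GraphML copy is written when
    ``graphml_path`` is given.
    """
    mode_of: dict[str, str] = {}
    if mode_table is not None and len(mode_table):
        for mirna_id, sub in mode_table.groupby("mirna_id"):
            non_cons = sub.loc[sub["mode"] != "conserved", "mode"]
            mode_of[mirna_id] = non_cons.iloc[0] if len(non_cons) else "conserved"

    with open(sif_path, "w") as fh:
        for e in edges:
            fh.write(f"{e.mirna_id}\trepresses\t{e.gene_id}\n")

    rows = []
    seen = set()
    for e in edges:
        if e.mirna_id not in seen:
            seen.add(e.mirna_id)
            rows.append(
                {"node": e.mirna_id, "type": "miRNA",
                 "mode": mode_of.get(e.mirna_id, "unclassified")}
            )
        if e.gene_id not in seen:
            seen.add(e.gene_id)
            rows.append({"node": e.gene_id, "type": "gene", "mode": ""})
    pd.DataFrame(rows, columns=["node", "type", "mode"]).to_csv(
        attrs_path, sep="\t", index=False
    )

    if graphml_path is not None:
        import networkx as nx

        g = nx.DiGraph()
        for row in rows:
            g.add_node(row["node"], type=row["type"], mode=row["mode"])
        for e in edges:
            g.add_edge(e.mirna_id, e.gene_id, r=e.r, interaction="represses")
        nx.write_graphml(g, graphml_path)
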