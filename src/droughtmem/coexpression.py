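"""Ortholog mapping and correlation-threshold co-expression networks.

A query transcript is mapped to its counterpart in a reference species by
filtering a tabular alignment file (12-column BLAST-like dialect) at a
score threshold (default 70, the bit-score column) and keeping the best
hit per query. Co-expression uses a depth-0 search: all pairwise Pearson
correlations are computed within the supplied gene set only (no expansion
to outside neighbors), edges are kept at |r| >= 0.65, and clusters are the
connected components. For tree views the correlation matrix is converted
to distances d = 1 - r, clustered by average linkage and exported as a
Newick string with branch lengths.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class OrthologMap:
    """Best-hit query -> subject mapping above a score threshold."""

    hits: pd.DataFrame  # columns: query, subject, score (retained rows)
    best: dict[str, str]  # query -> subject
    score_threshold: float
    n_malformed: int = 0

    def __getitem__(self, query: str) -> str:
        return self.best[query]

    def __contains__(self, query: str) -> bool:
        return query in self.best

    def __len__(self) -> int:
        return len(self.best)


def map_orthologs(
    alignment_source,
    score_threshold: float = 70.0,
    score_column: str = "bitscore",
) -> OrthologMap:
    """Filter a tabular alignment at ``score_threshold`` and keep one best
    subject per query (highest score; ties break lexicographically).

    Accepts a path, text, file-like object or DataFrame. Tabular rows with
    fewer than 12 columns or a non-numeric score are skipped and counted.
    ``score_column`` selects which column is thresholded (the default is
    the alignment bit score).
    """
    if isinstance(alignment_source, pd.DataFrame):
        df = alignment_source.copy()
        if "query" not in df.columns:
            df.columns = BLAST_COLUMNS[: len(df.columns)]
            df = df.rename(columns={"qseqid": "query", "sseqid": "subject"})
        n_malformed = 0
    else:
        is_text = isinstance(alignment_source, str) and (
            "\n" in alignment_source
            or "\t" in alignment_source
            or alignment_source == ""
        )
        if isinstance(alignment_source, (str, os.PathLike)) and not is_text:
            with open(alignment_source) as fh:
                lines = fh.read().splitlines()
        elif isinstance(alignment_source, str):
            lines = alignment_source.splitlines()
        else:
            lines = alignment_source.read().splitlines()
        rows, n_malformed = [], 0
        for line in lines:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                n_malformed += 1
                continue
            try:
                row = dict(zip(BLAST_COLUMNS, cols))
                row["bitscore"] = float(row["bitscore"])
                row["evalue"] = float(row["evalue"])
                row["pident"] = float(row["pident"])
            except ValueError:
                n_malformed += 1
                continue
            rows.append(row)
        df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
        df = df.rename(columns={"qseqid": "query", "sseqid": "subject"})
    if len(df) == 0:
        return OrthologMap(
            hits=pd.DataFrame(columns=["query", "subject", "score"]),
            best={},
            score_threshold=score_threshold,
            n_malformed=n_malformed,
        )
    df["score"] = pd.to_numeric(df[score_column if score_column in df.columns
                                   else "bitscore"])
    kept = df.loc[df["score"] >= score_threshold, ["query", "subject", "score"]]
    best: dict[str, str] = {}
    # highest score wins; ties -> lexicographically smallest subject
    for query, grp in kept.groupby("query"):
        top = grp[grp["score"] == grp["score"].max()]
        best[str(query)] = str(top["subject"].min())
    return OrthologMap(
        hits=kept.reset_index(drop=True),
        best=best,
        score_threshold=score_threshold,
        n_malformed=n_malformed,
    )


@dataclass
class CoexpressionNetwork:
    """Thresholded Pearson correlation graph over a fixed gene set."""

    graph: nx.Graph
    correlations: pd.DataFrame  # full symmetric r matrix (included genes)
    threshold: float
    excluded: list[str] = field(default_factory=list)  # constant-profile genes

    @property
    def components(self) -> list[frozenset]:
        """Connected components, largest first (ties by smallest member)."""
        comps = [frozenset(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), min(c)))

    def edges(self) -> pd.DataFrame:
        rows = [
            {"gene_i": min(u, v), "gene_j": max(u, v), "r": d["r"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return (
            pd.DataFrame(rows, columns=["gene_i", "gene_j", "r"])
            .sort_values(["gene_i", "gene_j"])
            .reset_index(drop=True)
        )

    def components_frame(self) -> pd.DataFrame:
        rows = []
        for rank, comp in enumerate(self.components, start=1):
            for gene in sorted(comp):
                rows.append({"component": rank, "size": len(comp), "gene": gene})
        return pd.DataFrame(rows, columns=["component", "size", "gene"])


def pearson_network(
    expr: pd.DataFrame, threshold: float = 0.65
) -> CoexpressionNetwork:
    """Depth-0 co-expression network over the supplied gene set.

    ``expr`` holds genes in rows and observations in columns (>= 3).
    All pairwise Pearson correlations are computed within the set; an edge
    joins i and j when |r_ij| >= threshold. Genes with constant profiles
    (undefined r) are excluded with a record.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 observations per gene")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    excluded = list(expr.index[sd == 0])
    keep = expr.index[sd > 0]
    values = expr.loc[keep].to_numpy(dtype=float)
    graph = nx.Graph()
    graph.add_nodes_from(keep)
    if len(keep) >= 2:
        r = np.corrcoef(values)
        np.fill_diagonal(r, 1.0)
        corr = pd.DataFrame(r, index=keep, columns=keep)
        ii, jj = np.where(np.triu(np.abs(r) >= threshold, k=1))
        for i, j in zip(ii, jj):
            graph.add_edge(keep[i], keep[j], r=float(r[i, j]))
    else:
        corr = pd.DataFrame(np.ones((len(keep), len(keep))),
                            index=keep, columns=keep)
    return CoexpressionNetwork(
        graph=graph, correlations=corr, threshold=threshold, excluded=excluded
    )


def _tree_to_newick(node, labels: Sequence[str]) -> str:
    """Serialize a scipy ClusterNode tree; each branch length is half the
    merge-height difference so the tree is ultrametric in d/2."""

    def recurse(n, parent_height: float) -> str:
        length = (parent_height - n.dist) / 2.0
        if n.is_leaf():
            return f"{labels[n.id]}:{length:g}"
        left = recurse(n.get_left(), n.dist)
        right = recurse(n.get_right(), n.dist)
        return f"({left},{right}):{length:g}"

    if node.is_leaf():
        return f"{labels[node.id]}:0;"
    left = recurse(node.get_left(), node.dist)
    right = recurse(node.get_right(), node.dist)
    return f"({left},{right});"


def cluster_tree(
    source: CoexpressionNetwork | pd.DataFrame,
    use_abs: bool = False,
) -> str:
    """Average-linkage hierarchical clustering of the correlation matrix,
    exported as a Newick string with branch lengths.

    Distances are d = 1 - r by default (anti-correlated genes are the
    farthest apart); ``use_abs=True`` switches to d = 1 - |r|. Leaf order
    is deterministic for identical inputs.
    """
    corr = (
        source.correlations
        if isinstance(source, CoexpressionNetwork)
        else source
    )
    labels = [str(x) for x in corr.index]
    if len(labels) == 0:
        raise ValueError("empty correlation matrix")
    if len(labels) == 1:
        return f"{labels[0]}:0;"
    r = corr.to_numpy(dtype=float)
    d = 1.0 - (np.abs(r) if use_abs else r)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # enforce exact symmetry
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    root = hierarchy.to_tree(Z)
    return _tree_to_newick(root, labels)
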