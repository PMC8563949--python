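"""DEG-geneset overlap networks, hypergeometric enrichment, regulatory networks.

Three network-flavoured summaries of the aging DEG tables:

* ``enrich_terms`` — one-sided hypergeometric enrichment of a gene list
  against a user-supplied term -> genes annotation, BH-corrected;
* ``overlap_network`` — the bipartite network between aging DEGs and curated
  gene sets (GenAge, AMD, RP...), where a gene node is weighted by the
  number of cell types in which it is a DEG and edges carry the mean signed
  log2 fold change over those cell types;
* ``regulatory_network`` — candidate master regulators: TF -> target edges
  weighted by |Spearman correlation| across one cell type's cells, with
  regulators ranked by connection count (top 10 reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .qcnorm import ExpressionMatrix
from .scores import GeneSetCollection

logger = logging.getLogger(__name__)


def enrich_terms(
    gene_list: list[str],
    annotation: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``gene_list`` per term.

    With N = |universe|, K = term genes in universe, n = |gene_list| and
    k = overlap, p = P(X >= k) for X ~ Hypergeom(N, K, n).  Rows are sorted
    by p (ties by term name); q is the BH-adjusted p over all terms.
    """
    if not gene_list:
        raise ValueError("gene_list is empty")
    if not annotation:
        raise ValueError("term annotation is empty")
    universe_set = set(universe)
    missing = set(gene_list) - universe_set
    if missing:
        raise ValueError(f"gene_list not contained in universe: {sorted(missing)[:5]}")
    N, n = len(universe_set), len(set(gene_list))
    rows = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & universe_set
        K = len(term_genes)
        k = len(term_genes & set(gene_list))
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term": term, "overlap": k, "term_size": K, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


@dataclass
class OverlapNetwork:
    """Bipartite DEG <-> geneset network (one direction: up or down)."""

    direction: str
    nodes: pd.DataFrame  # gene, n_cell_types, mean_log2fc
    edges: pd.DataFrame  # gene, geneset, avg_log2fc
    genesets: list[str]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.nodes.itertuples():
            g.add_node(
                row.gene, kind="gene", n_cell_types=row.n_cell_types,
                mean_log2fc=row.mean_log2fc,
            )
        for name in self.genesets:
            g.add_node(name, kind="geneset")
        for row in self.edges.itertuples():
            g.add_edge(row.gene, row.geneset, avg_log2fc=row.avg_log2fc)
        return g

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.nodes.to_csv(prefix.with_suffix(".nodes.csv"), index=False)
        self.edges.to_csv(prefix.with_suffix(".edges.csv"), index=False)
        nx.write_graphml(self.to_networkx(), prefix.with_suffix(".graphml"))


def overlap_network(
    degs: pd.DataFrame, sets: GeneSetCollection, direction: str
) -> OverlapNetwork:
    """Genes that are aging DEGs (in ``direction``) and belong to >= 1 set.

    Node weight = number of cell types where the gene is a DEG in that
    direction; node/edge log2fc = mean signed log2fc over exactly those
    cell types.  Output rows are sorted for stable serialization.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if degs.empty:
        raise ValueError("DEG table is empty")
    called = degs[(degs.get("is_deg", degs["fdr"] < 0.05)) & (degs["direction"] == direction)]
    membership = [
        (g, name) for name in sets.names() for g in sets[name]
    ]
    member_df = pd.DataFrame(membership, columns=["gene", "geneset"])
    stats = (
        called.groupby("gene")
        .agg(n_cell_types=("cell_type", "nunique"), mean_log2fc=("log2fc", "mean"))
        .reset_index()
    )
    nodes = stats[stats["gene"].isin(member_df["gene"])].sort_values("gene")
    edges = (
        member_df.merge(nodes, on="gene")
        .rename(columns={"mean_log2fc": "avg_log2fc"})[["gene", "geneset", "avg_log2fc"]]
        .sort_values(["gene", "geneset"])
        .reset_index(drop=True)
    )
    return OverlapNetwork(
        direction=direction,
        nodes=nodes.reset_index(drop=True),
        edges=edges,
        genesets=sorted(set(edges["geneset"])),
    )


@dataclass
class RegulatoryNetwork:
    cell_type: str
    edges: pd.DataFrame  # regulator, target, weight
    connections: pd.DataFrame  # regulator, n_connections (ranked)
    top_regulators: list[str] = field(default_factory=list)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.edges.itertuples():
            g.add_edge(row.regulator, row.target, weight=row.weight)
        return g

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.edges.to_csv(prefix.with_suffix(".edges.csv"), index=False)
        self.connections.to_csv(prefix.with_suffix(".connections.csv"), index=False)
        if len(self.edges):
            nx.write_graphml(self.to_networkx(), prefix.with_suffix(".graphml"))


def regulatory_network(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    cell_type: str,
    deg_genes: list[str],
    tf_list: list[str],
    min_abs_corr: float = 0.3,
    cell_type_col: str = "cell_type",
    min_cells: int = 10,
) -> RegulatoryNetwork:
    """Correlation-based TF -> target network within one cell type.

    Candidate regulators are ``tf_list`` members that are also aging DEGs;
    an edge TF -> target (target in ``deg_genes``, TF != target) is kept when
    |Spearman rho| across the type's cells >= ``min_abs_corr``; its weight is
    that absolute correlation.  Regulators are ranked by connection count,
    ties broken by name; the ten best are reported.
    """
    meta = annotation.set_index("cell_id").loc[expr.cell_ids]
    mask = (meta[cell_type_col] == cell_type).to_numpy()
    if mask.sum() < min_cells:
        raise ValueError(
            f"cell type {cell_type!r} has {int(mask.sum())} cells; needs >= {min_cells}"
        )
    present = set(expr.gene_ids)
    targets = sorted(set(deg_genes) & present)
    regulators = sorted(set(tf_list) & set(targets))
    empty_edges = pd.DataFrame(columns=["regulator", "target", "weight"])
    empty_conn = pd.DataFrame(columns=["regulator", "n_connections"])
    if not regulators:
        logger.warning("no candidate regulators (tf_list ∩ deg_genes empty)")
        return RegulatoryNetwork(cell_type, empty_edges, empty_conn, [])
    block = expr.values[np.ix_(expr.gene_index(targets), np.flatnonzero(mask))]
    # rank-transform once, then all pairwise correlations in one matmul
    ranks = pd.DataFrame(block.T).rank().to_numpy()
    ranks -= ranks.mean(axis=0)
    norm = np.sqrt((ranks**2).sum(axis=0))
    norm[norm == 0] = np.inf  # constant genes correlate with nothing
    rho = (ranks.T @ ranks) / np.outer(norm, norm)
    pos = {g: i for i, g in enumerate(targets)}
    rows = []
    for tf in regulators:
        for target in targets:
            if target == tf:
                continue
            w = abs(float(rho[pos[tf], pos[target]]))
            if w >= min_abs_corr:
                rows.append({"regulator": tf, "target": target, "weight": w})
    edges = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    if edges.empty:
        return RegulatoryNetwork(cell_type, empty_edges, empty_conn, [])
    conn = (
        edges.groupby("regulator").size().rename("n_connections").reset_index()
        .sort_values(["n_connections", "regulator"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return RegulatoryNetwork(
        cell_type=cell_type,
        edges=edges.sort_values(["regulator", "target"]).reset_index(drop=True),
        connections=conn,
        top_regulators=conn["regulator"].head(10).tolist(),
    )
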