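"""Variable-gene selection, clustering, marker ranking and cluster annotation.

Clustering is PCA (default 20 components) on a highly-variable-gene
submatrix followed by k-means with a caller-supplied cluster number and
seed, so runs are exactly reproducible.  Cell-type markers are ranked by
"average difference": mean log-normalized expression in the type minus the
mean in all other cells, one-vs-rest.  Clusters are annotated by matching
against reference marker lists (e.g. TYR/RPE65 for RPE, PDE6A for rods).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .qcnorm import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-cell cluster ID, contiguous ints from 0
    embedding: np.ndarray  # per-cell 2D coordinates (visualization only)
    n_clusters: int
    seed: int


def select_hvgs(expr: ExpressionMatrix, n_top: int, n_bins: int = 20) -> list[str]:
    """Top ``n_top`` genes by mean-binned standardized dispersion.

    Dispersion is variance/mean of log-normalized expression; genes are
    binned by mean expression and dispersions z-scored within each bin, so
    highly expressed genes do not dominate.  Deterministic: ties break by
    gene order.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    means = expr.values.mean(axis=1)
    variances = expr.values.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(means > 0, variances / np.maximum(means, 1e-12), 0.0)
    df = pd.DataFrame({"mean": means, "disp": dispersion})
    df["bin"] = pd.cut(df["mean"], bins=min(n_bins, max(1, df["mean"].nunique())), labels=False)
    grouped = df.groupby("bin")["disp"]
    mu, sd = grouped.transform("mean"), grouped.transform("std").replace(0, np.nan)
    z = ((df["disp"] - mu) / sd).fillna(0.0).to_numpy()
    z[variances == 0] = -np.inf  # constant genes are never variable
    if n_top > len(expr.gene_ids):
        logger.warning(
            "n_top=%d exceeds gene count %d; returning all genes", n_top, len(expr.gene_ids)
        )
        n_top = len(expr.gene_ids)
    order = np.lexsort((np.arange(len(z)), -z))  # stable: score desc, then gene order
    return [expr.gene_ids[i] for i in order[:n_top]]


def embed_cluster(
    expr: ExpressionMatrix,
    hvgs: list[str],
    n_clusters: int,
    seed: int = 0,
    n_components: int = 20,
    embedding: str = "pca",
) -> ClusterResult:
    """PCA on the HVG submatrix then k-means.

    The 2D ``embedding`` (first two PCs, or t-SNE of the PC space when
    ``embedding="tsne"``) is for visualization only; cluster labels always
    come from k-means on the full PC space.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    n_cells = len(expr.cell_ids)
    if n_clusters > n_cells:
        raise ValueError(f"n_clusters={n_clusters} exceeds cell count {n_cells}")
    sub = expr.values[expr.gene_index(hvgs)].T  # cells x genes
    n_components = min(n_components, sub.shape[0], sub.shape[1])
    pcs = PCA(n_components=n_components, random_state=seed).fit_transform(sub)
    labels = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(pcs)
    if embedding == "tsne":
        from sklearn.manifold import TSNE

        coords = TSNE(
            n_components=2, random_state=seed,
            perplexity=min(30.0, max(2.0, (n_cells - 1) / 3)),
        ).fit_transform(pcs)
    elif embedding == "pca":
        coords = pcs[:, : min(2, n_components)]
    else:
        raise ValueError(f"embedding must be 'pca' or 'tsne', got {embedding!r}")
    return ClusterResult(
        labels=labels.astype(int),
        embedding=coords,
        n_clusters=n_clusters,
        seed=seed,
    )


def rank_markers(
    expr: ExpressionMatrix, labels: np.ndarray | list, top_n: int = 100
) -> pd.DataFrame:
    """One-vs-rest marker ranking by average difference in log expression.

    avg_diff(gene, type) = mean expression in the type's cells minus mean in
    all other cells.  Per type the ``top_n`` genes with largest avg_diff are
    reported, ranks 1..top_n with avg_diff non-increasing; ties break by
    gene ID for determinism.
    """
    labels = np.asarray(labels)
    uniq = sorted(pd.unique(labels), key=str)
    if len(uniq) < 2:
        raise ValueError("rank_markers needs >= 2 distinct labels")
    rows = []
    for lab in uniq:
        mask = labels == lab
        if mask.sum() < 2:
            logger.warning("label %s has < 2 cells; statistics still computed", lab)
        diff = expr.values[:, mask].mean(axis=1) - expr.values[:, ~mask].mean(axis=1)
        order = np.lexsort((np.asarray(expr.gene_ids), -diff))[: min(top_n, len(diff))]
        for rank, gi in enumerate(order, start=1):
            rows.append(
                {
                    "gene": expr.gene_ids[gi],
                    "cell_type": lab,
                    "avg_diff": float(diff[gi]),
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows)


def annotate_clusters(
    expr: ExpressionMatrix,
    labels: np.ndarray | list,
    reference: dict[str, list[str]],
    min_score: float = 0.25,
) -> dict:
    """Assign each cluster the reference type with highest mean marker z-score.

    Each gene is z-scored across all cells; a cluster's score for a type is
    the mean z of that type's reference markers over the cluster's cells.
    Clusters whose best score is below ``min_score`` are labeled "unknown".
    Exact ties go to the lexicographically smaller type name (logged).
    """
    if not reference:
        raise ValueError("reference marker map is empty")
    labels = np.asarray(labels)
    present_genes = set(expr.gene_ids)
    z = scipy.stats.zscore(expr.values, axis=1)
    z = np.nan_to_num(z)  # constant genes carry no information
    assignment = {}
    for cluster in sorted(pd.unique(labels), key=str):
        mask = labels == cluster
        scores = {}
        for ctype, markers in sorted(reference.items()):
            idx = expr.gene_index([g for g in markers if g in present_genes])
            if len(idx) == 0:
                continue
            scores[ctype] = float(z[np.ix_(idx, np.flatnonzero(mask))].mean())
        if not scores:
            assignment[cluster] = "unknown"
            continue
        best = max(scores.values())
        winners = sorted(t for t, s in scores.items() if s == best)
        if len(winners) > 1:
            logger.warning("cluster %s: score tie between %s; taking %s", cluster, winners, winners[0])
        assignment[cluster] = winners[0] if best >= min_score else "unknown"
    return assignment


def cross_species_correlation(
    profiles_by_species: dict[str, dict[str, pd.Series]],
    ortholog_map: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman correlation of matched cell-type profiles across species.

    ``profiles_by_species`` maps species -> {cell type -> mean expression
    Series indexed by that species' gene IDs}; ``ortholog_map`` is a table
    with one column per species giving matched ortholog IDs per row.

    Returns rows (species_a, species_b, cell_type, spearman_r) for every
    species pair and every cell type shared by the pair.
    """
    species = sorted(profiles_by_species)
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    rows = []
    for a, b in itertools.combinations(species, 2):
        if a not in ortholog_map.columns or b not in ortholog_map.columns:
            raise ValueError(f"ortholog map lacks a column for {a!r} or {b!r}")
        pairs = ortholog_map[[a, b]].dropna()
        shared_types = sorted(set(profiles_by_species[a]) & set(profiles_by_species[b]))
        for ctype in shared_types:
            pa, pb = profiles_by_species[a][ctype], profiles_by_species[b][ctype]
            usable = pairs[pairs[a].isin(pa.index) & pairs[b].isin(pb.index)]
            if len(usable) < 2:
                raise ValueError(
                    f"fewer than 2 shared orthologs between {a} and {b} for {ctype}"
                )
            r = scipy.stats.spearmanr(
                pa[usable[a]].to_numpy(), pb[usable[b]].to_numpy()
            ).statistic
            rows.append(
                {"species_a": a, "species_b": b, "cell_type": ctype, "spearman_r": float(r)}
            )
    return pd.DataFrame(rows)


def type_mean_profiles(
    expr: ExpressionMatrix, labels: np.ndarray | list
) -> dict[str, pd.Series]:
    """Per-type mean expression vectors, the input unit of cross-species maps."""
    labels = np.asarray(labels)
    return {
        str(lab): pd.Series(
            expr.values[:, labels == lab].mean(axis=1), index=expr.gene_ids
        )
        for lab in sorted(pd.unique(labels), key=str)
    }
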