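"""Per-cell gene-set scores and transcriptional-noise quantification.

Two summary statistics used throughout aging single-cell studies live here:

* the SASP-style gene-set score — the plain average normalized expression of
  a gene set in each cell (no z-scoring, no control-set subtraction), so the
  score of a set whose genes rise with age rises with age;
* the coefficient of variation (CV) of each gene across the cells of one
  (cell type, age group) stratum — elevated CV in old cells is read as
  elevated transcriptional noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .qcnorm import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene lists (SASP, GenAge, AMD, RP, TFs, markers...)."""

    sets: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not isinstance(g, str) or not g for g in genes):
                raise ValueError(f"gene set {name!r} contains empty/non-string genes")
        for name in self.sets:
            self.provenance.setdefault(name, "unspecified")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read tab-delimited gene sets: name <tab> description <tab> gene..."""
    sets: dict[str, list[str]] = {}
    prov: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line needs >= 3 fields: {line[:60]!r}")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = genes
        prov[name] = desc
    return GeneSetCollection(sets, prov)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.provenance.get(name, "unspecified"), *genes])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def geneset_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Score every cell for every gene set.

    score(cell, set) = mean normalized expression over the set's genes that
    are present in the matrix.  Set genes missing from the matrix are dropped
    with a log message; a set with no present genes is an error.

    Returns one row per (cell, set): cell_id, set, score, age_group, cell_type.
    """
    meta = annotation.set_index("cell_id").loc[expr.cell_ids]
    records = []
    for name in sets.names():
        present = [g for g in sets[name] if g in set(expr.gene_ids)]
        missing = len(sets[name]) - len(present)
        if not present:
            raise KeyError(f"gene set {name!r} has no genes present in the matrix")
        if missing:
            logger.info("gene set %s: %d genes absent from matrix, dropped", name, missing)
        idx = expr.gene_index(present)
        scores = expr.values[idx].mean(axis=0)
        records.append(
            pd.DataFrame(
                {
                    "cell_id": expr.cell_ids,
                    "set": name,
                    "score": scores,
                    "age_group": meta["age_group"].to_numpy(),
                    "cell_type": meta.get(
                        "cell_type", pd.Series("all", index=meta.index)
                    ).to_numpy(),
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def score_group_comparison(
    scores: pd.DataFrame, stratify: str | None = None
) -> pd.DataFrame:
    """Compare score distributions between age groups.

    Per gene set and (optionally) per stratum column (e.g. ``cell_type``):
    group medians, median difference (old - young) and a two-sided Wilcoxon
    rank-sum P value.  Strata where one age group is absent are skipped with
    a log message.  Output is ordered by (set, stratum).
    """
    if not {"young", "old"} <= set(scores["age_group"]):
        raise ValueError("both age groups must be present")
    rows = []
    group_cols = ["set"] + ([stratify] if stratify else [])
    for keys, sub in scores.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        young = sub.loc[sub["age_group"] == "young", "score"].to_numpy()
        old = sub.loc[sub["age_group"] == "old", "score"].to_numpy()
        if len(young) == 0 or len(old) == 0:
            logger.info("stratum %s has a single age group; skipped", keys)
            continue
        p = scipy.stats.mannwhitneyu(old, young, alternative="two-sided").pvalue
        row = {"set": keys[0]}
        if stratify:
            row[stratify] = keys[1]
        row.update(
            median_young=float(np.median(young)),
            median_old=float(np.median(old)),
            delta=float(np.median(old) - np.median(young)),
            p=float(p),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def transcriptional_noise_cv(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    min_mean: float = 0.1,
    min_cells: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-(cell type, age group) gene-wise coefficients of variation.

    Within each stratum, every gene whose mean normalized expression is
    >= ``min_mean`` gets cv = sample SD (ddof=1) / mean.  Strata with fewer
    than ``min_cells`` cells are skipped with a log message.

    Returns (cv_table, summary, comparison):
      cv_table    — rows (cell_type, age_group, gene, cv)
      summary     — per stratum: median cv, n genes
      comparison  — per cell type: paired across-genes Wilcoxon of old vs
                    young cv on the gene intersection
    """
    meta = annotation.set_index("cell_id").loc[expr.cell_ids]
    cv_rows, summary_rows = [], []
    per_stratum: dict[tuple[str, str], pd.Series] = {}
    for (ctype, group), sub in meta.groupby(["cell_type", "age_group"], sort=True):
        mask = meta.index.isin(sub.index)
        if mask.sum() < min_cells:
            logger.info("stratum (%s, %s): %d cells < %d, skipped", ctype, group, mask.sum(), min_cells)
            continue
        block = expr.values[:, mask]
        means = block.mean(axis=1)
        keep = means >= min_mean
        sds = block[keep].std(axis=1, ddof=1)
        cvs = pd.Series(
            sds / means[keep], index=np.asarray(expr.gene_ids)[keep], name="cv"
        )
        per_stratum[(str(ctype), str(group))] = cvs
        cv_rows.append(
            pd.DataFrame(
                {
                    "cell_type": ctype,
                    "age_group": group,
                    "gene": cvs.index,
                    "cv": cvs.to_numpy(),
                }
            )
        )
        summary_rows.append(
            {
                "cell_type": ctype,
                "age_group": group,
                "median_cv": float(cvs.median()),
                "n_genes": int(keep.sum()),
            }
        )
    cv_table = (
        pd.concat(cv_rows, ignore_index=True)
        if cv_rows
        else pd.DataFrame(columns=["cell_type", "age_group", "gene", "cv"])
    )
    summary = pd.DataFrame(summary_rows)
    comp_rows = []
    for ctype in sorted({t for t, _ in per_stratum}):
        if (ctype, "young") not in per_stratum or (ctype, "old") not in per_stratum:
            continue
        young, old = per_stratum[(ctype, "young")], per_stratum[(ctype, "old")]
        shared = young.index.intersection(old.index)
        if len(shared) < 2:
            continue
        diffs = old[shared].to_numpy() - young[shared].to_numpy()
        if np.allclose(diffs, 0):
            p = 1.0
        else:
            p = float(scipy.stats.wilcoxon(diffs).pvalue)
        comp_rows.append(
            {
                "cell_type": ctype,
                "n_genes": len(shared),
                "median_cv_young": float(young[shared].median()),
                "median_cv_old": float(old[shared].median()),
                "p": p,
            }
        )
    return cv_table, summary, pd.DataFrame(comp_rows)
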