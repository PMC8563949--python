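"""Count-matrix containers, readers/writers, cell/gene QC and log-normalization.

The pipeline works on a genes x cells UMI count matrix plus a per-cell
metadata table (donor, age group, sex, tissue layer).  Counts are stored
sparse (CSR); normalized expression is dense natural-log values, since all
downstream statistics (marker ranking, DEG tests, scores, correlations)
operate on modest desk-scale matrices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

AGE_GROUPS = ("young", "old")
METADATA_COLUMNS = ("cell_id", "donor", "age_group", "sex", "layer")


class FormatError(ValueError):
    """Malformed input file (dimension/ID mismatch, bad MTX header...)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a contract (negative counts...)."""


class EmptyResultError(RuntimeError):
    """An operation removed every cell; downstream analysis is impossible."""


def _check_ids(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} IDs: {dupes[:5]}")


@dataclass
class CountMatrix:
    """Integer UMI counts, genes x cells, with unique gene and cell IDs."""

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_ids(self.gene_ids, "gene")
        _check_ids(self.cell_ids, "cell")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        if not np.allclose(self.values.data, np.round(self.values.data)):
            raise ValidationError("count matrix contains non-integer entries")
        self.values.data = np.asarray(np.round(self.values.data), dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected (count > 0) genes in each cell."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()


@dataclass
class ExpressionMatrix:
    """Natural-log normalized expression, genes x cells (dense)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError("expression shape does not match ID lists")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValidationError("expression must be finite and non-negative")
        _check_ids(self.gene_ids, "gene")
        _check_ids(self.cell_ids, "cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, genes: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            self.values[:, mask],
            self.gene_ids,
            [c for c, m in zip(self.cell_ids, mask) if m],
        )


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 500
    min_counts_per_cell: int = 1000
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.min_counts_per_cell, self.min_cells_per_gene) < 0:
            raise ValidationError("QC thresholds must be >= 0")


@dataclass
class QCReport:
    thresholds: QCThresholds
    n_cells_in: int
    n_cells_kept: int
    n_genes_in: int
    n_genes_kept: int
    per_cell: pd.DataFrame = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": vars(self.thresholds),
            "n_cells_in": self.n_cells_in,
            "n_cells_kept": self.n_cells_kept,
            "n_cells_removed": self.n_cells_in - self.n_cells_kept,
            "n_genes_in": self.n_genes_in,
            "n_genes_kept": self.n_genes_kept,
            "n_genes_removed": self.n_genes_in - self.n_genes_kept,
            "per_cell": self.per_cell.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, format: str = "mtx") -> CountMatrix:
    """Read a count matrix.

    ``mtx``: *path* is a directory holding ``matrix.mtx`` (genes x cells
    triplets) plus ``genes.tsv`` and ``barcodes.tsv`` (one ID per line).
    ``csv``: *path* is a dense CSV whose header row gives cell IDs and whose
    first column gives gene IDs.
    """
    path = Path(path)
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path / "matrix.mtx")
        except (ValueError, OSError) as exc:
            raise FormatError(f"cannot parse {path / 'matrix.mtx'}: {exc}") from exc
        genes = (path / "genes.tsv").read_text().split()
        cells = (path / "barcodes.tsv").read_text().split()
        return CountMatrix(sp.csr_matrix(mat), genes, cells)
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        if not df.map(np.isreal).all().all():
            raise ValidationError("CSV contains non-numeric entries")
        return CountMatrix(
            sp.csr_matrix(df.to_numpy()), df.index.tolist(), df.columns.tolist()
        )
    raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'csv'")


def write_counts(counts: CountMatrix, path: str | Path, format: str = "mtx") -> None:
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", counts.values.tocoo(), field="integer")
        (path / "genes.tsv").write_text("\n".join(counts.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    elif format == "csv":
        pd.DataFrame(
            counts.dense(), index=counts.gene_ids, columns=counts.cell_ids
        ).to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-cell metadata TSV and validate required columns."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    bad = set(meta["age_group"]) - set(AGE_GROUPS)
    if bad:
        raise ValidationError(f"age_group must be one of {AGE_GROUPS}, got {sorted(bad)}")
    _check_ids(meta["cell_id"].tolist(), "cell")
    return meta.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def filter_cells(
    counts: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, QCReport]:
    """Drop low-quality cells, then rarely-detected genes.

    A cell is kept when its detected-gene count and total UMI count both meet
    their thresholds; genes are filtered afterwards so that gene prevalence
    reflects surviving cells only.
    """
    thresholds = thresholds or QCThresholds()
    n_genes = counts.genes_per_cell()
    n_counts = counts.counts_per_cell()
    cell_pass = (n_genes >= thresholds.min_genes_per_cell) & (
        n_counts >= thresholds.min_counts_per_cell
    )
    per_cell = pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "n_genes": n_genes,
            "n_counts": n_counts,
            "passed": cell_pass,
        }
    )
    if not cell_pass.any():
        raise EmptyResultError(
            "all cells removed by QC; relax min_genes_per_cell/min_counts_per_cell"
        )
    kept = counts.values[:, cell_pass]
    gene_prevalence = np.asarray((kept > 0).sum(axis=1)).ravel()
    gene_pass = gene_prevalence >= thresholds.min_cells_per_gene
    filtered = CountMatrix(
        kept[gene_pass],
        [g for g, m in zip(counts.gene_ids, gene_pass) if m],
        [c for c, m in zip(counts.cell_ids, cell_pass) if m],
    )
    report = QCReport(
        thresholds=thresholds,
        n_cells_in=len(counts.cell_ids),
        n_cells_kept=len(filtered.cell_ids),
        n_genes_in=len(counts.gene_ids),
        n_genes_kept=len(filtered.gene_ids),
        per_cell=per_cell,
    )
    logger.info(
        "QC kept %d/%d cells and %d/%d genes",
        report.n_cells_kept, report.n_cells_in, report.n_genes_kept, report.n_genes_in,
    )
    return filtered, report


def normalize(counts: CountMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Depth-normalize and natural-log transform: ln(count * scale / total + 1)."""
    totals = counts.counts_per_cell().astype(float)
    if (totals == 0).any():
        raise EmptyResultError(
            "cells with zero total counts present; run filter_cells first"
        )
    dense = counts.dense().astype(float)
    expr = np.log1p(dense * scale / totals[np.newaxis, :])
    return ExpressionMatrix(expr, counts.gene_ids, counts.cell_ids)
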