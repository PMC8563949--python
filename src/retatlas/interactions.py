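"""Ligand-receptor interaction activity per age group and young->old deltas.

An ordered (sender type, receiver type, ligand-receptor pair) interaction is
"active" in an age group when, among that group's cells, the ligand is
expressed in at least ``min_frac`` of the sender type's cells with mean
normalized expression at least ``min_mean``, and the receptor satisfies the
same two thresholds in the receiver type (CellPhoneDB-style convention;
values exactly at threshold count as active).  Comparing the active sets of
the two age groups classifies each interaction as newborn (old only),
disappeared (young only) or unchanged (both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .qcnorm import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_FRAC = 0.1
DEFAULT_MIN_MEAN = 0.1


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor must be non-empty")

    @property
    def label(self) -> str:
        return f"{self.ligand}-{self.receptor}"


@dataclass
class InteractionRecord:
    sender: str
    receiver: str
    pair: str
    active_young: bool
    active_old: bool

    @property
    def delta_class(self) -> str:
        if self.active_old and not self.active_young:
            return "newborn"
        if self.active_young and not self.active_old:
            return "disappeared"
        if self.active_young and self.active_old:
            return "unchanged"
        return "absent"


def read_lr_pairs(path: str | Path) -> list[LRPair]:
    """Read a two-column (ligand, receptor) CSV into LR pairs."""
    df = pd.read_csv(path)
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("LR database CSV needs 'ligand' and 'receptor' columns")
    return [LRPair(str(r.ligand), str(r.receptor)) for r in df.itertuples()]


def active_interactions(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    lr_db: list[LRPair],
    group: str,
    min_frac: float = DEFAULT_MIN_FRAC,
    min_mean: float = DEFAULT_MIN_MEAN,
    cell_type_col: str = "cell_type",
) -> set[tuple[str, str, str]]:
    """Active (sender, receiver, pair-label) triples for one age group.

    All ordered type pairs are evaluated, including sender == receiver.
    Pairs whose ligand or receptor is absent from the matrix are skipped
    with a log message; an empty result is valid.
    """
    if not lr_db:
        raise ValueError("LR database is empty")
    meta = annotation.set_index("cell_id").loc[expr.cell_ids]
    if group not in set(meta["age_group"]):
        raise ValueError(f"age group {group!r} not present")
    gmask = (meta["age_group"] == group).to_numpy()
    types = sorted(meta.loc[gmask, cell_type_col].unique(), key=str)
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}

    # per-type expressing fraction and mean for every gene, this group only
    frac, mean = {}, {}
    for t in types:
        tmask = gmask & (meta[cell_type_col] == t).to_numpy()
        block = expr.values[:, tmask]
        frac[t] = (block > 0).mean(axis=1)
        mean[t] = block.mean(axis=1)

    active: set[tuple[str, str, str]] = set()
    for pair in lr_db:
        if pair.ligand not in gene_pos or pair.receptor not in gene_pos:
            logger.info("pair %s skipped: gene absent from matrix", pair.label)
            continue
        li, ri = gene_pos[pair.ligand], gene_pos[pair.receptor]
        # tiny epsilon so values exactly at threshold count as active despite
        # floating-point summation error in the mean
        tol = 1e-9
        senders = [
            t for t in types
            if frac[t][li] >= min_frac - tol and mean[t][li] >= min_mean - tol
        ]
        receivers = [
            t for t in types
            if frac[t][ri] >= min_frac - tol and mean[t][ri] >= min_mean - tol
        ]
        for s in senders:
            for r in receivers:
                active.add((s, r, pair.label))
    return active


def classify_interactions(
    young_set: set[tuple[str, str, str]],
    old_set: set[tuple[str, str, str]],
) -> tuple[list[InteractionRecord], dict]:
    """Young vs old set algebra over active interactions.

    Returns the per-interaction records (for the union of both sets) plus a
    summary with per-(sender, receiver) class counts, per-type totals
    (counting both sent and received interactions), and overall totals.
    """
    records = [
        InteractionRecord(
            sender=s,
            receiver=r,
            pair=p,
            active_young=(s, r, p) in young_set,
            active_old=(s, r, p) in old_set,
        )
        for (s, r, p) in sorted(young_set | old_set)
    ]
    pair_counts: dict[tuple[str, str], dict[str, int]] = {}
    type_totals: dict[str, dict[str, int]] = {}
    totals = {
        "n_young": len(young_set),
        "n_old": len(old_set),
        "n_newborn": 0,
        "n_disappeared": 0,
        "n_unchanged": 0,
    }
    for rec in records:
        cls = rec.delta_class
        totals[f"n_{cls}"] += 1
        pc = pair_counts.setdefault(
            (rec.sender, rec.receiver), {"newborn": 0, "disappeared": 0, "unchanged": 0}
        )
        pc[cls] += 1
        for t in {rec.sender, rec.receiver}:
            tt = type_totals.setdefault(
                t, {"newborn": 0, "disappeared": 0, "unchanged": 0, "total": 0}
            )
            tt[cls] += 1
            tt["total"] += 1
    summary = {
        "totals": totals,
        "per_pair": pair_counts,
        "per_type": type_totals,
    }
    return records, summary


def records_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sender": r.sender,
                "receiver": r.receiver,
                "pair": r.pair,
                "active_young": r.active_young,
                "active_old": r.active_old,
                "class": r.delta_class,
            }
            for r in records
        ],
        columns=["sender", "receiver", "pair", "active_young", "active_old", "class"],
    )
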