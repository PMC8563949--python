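"""Synthetic STRT-seq-like retinal atlases with known ground truth.

Generates a genes x cells UMI count matrix for a configurable number of cell
types observed in young and old donors of both sexes across the two dissected
tissue layers (neural retina and RPE-choroid), with planted signal that every
downstream stage of the pipeline can be scored against:

* cell-type marker genes (mean multiplied by ``2**marker_log2fc`` in the
  marker's own type),
* aging DEGs (mean multiplied by ``2**(+-aging_log2fc)`` in old cells of one
  type; signs alternate gene by gene),
* a SASP gene set whose mean is multiplied by ``sasp_old_multiplier`` in all
  old cells,
* elevated old-cell overdispersion (transcriptional noise) in selected types,
* ligand-receptor pairs made active for chosen (sender, receiver, age group)
  combinations,
* optionally, a transcription factor whose per-cell activity co-drives a
  block of target genes (for regulatory-network recovery).

Counts are negative binomial with variance ``mean + dispersion * mean**2``
(gamma-Poisson mixture); donors multiply gene means by i.i.d. lognormal
factors, which adds inter-individual variation without breaking young/old
exchangeability when all effect multipliers are 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .qcnorm import CountMatrix, write_counts, write_metadata
from .scores import GeneSetCollection, write_gmt

# Canonical 15 retinal/choroidal cell types and their dissection layer.
CANONICAL_TYPES: dict[str, str] = {
    "Rod": "neural", "Cone": "neural", "Bipolar": "neural", "Mueller": "neural",
    "RGC": "neural", "MG": "neural",
    "RPE": "RPE-choroid", "Fib": "RPE-choroid", "EC": "RPE-choroid",
    "Gra": "RPE-choroid", "DC": "RPE-choroid", "Mac": "RPE-choroid",
    "T": "RPE-choroid", "B": "RPE-choroid", "Mast": "RPE-choroid",
}

# The interactions module calls a gene "expressed" above mean 0.1 / fraction
# 0.1 on normalized expression; planted-active LR genes use this count-scale
# mean, comfortably above, and inactive ones this near-zero mean.
LR_ACTIVE_MEAN = 4.0
LR_INACTIVE_MEAN = 0.01


class SimConfigError(ValueError):
    pass


@dataclass
class LRPlant:
    """A ligand-receptor pair planted between two cell-type indices."""

    sender: int
    receiver: int
    active_young: bool
    active_old: bool


def _default_lr_pairs(n_cell_types: int) -> list[LRPlant]:
    # one of each delta class: newborn, disappeared, unchanged, absent
    b = min(1, n_cell_types - 1)
    return [
        LRPlant(0, b, active_young=False, active_old=True),
        LRPlant(0, b, active_young=True, active_old=False),
        LRPlant(b, 0, active_young=True, active_old=True),
        LRPlant(b, 0, active_young=False, active_old=False),
    ]


@dataclass
class SimConfig:
    n_cell_types: int = 15
    cells_per_type_per_group: int = 40
    n_genes: int = 1500
    n_markers_per_type: int = 25
    marker_log2fc: float = 2.0
    n_aging_degs_per_type: int = 20
    aging_log2fc: float = 2.0
    sasp_set_size: int = 30
    sasp_old_multiplier: float = 1.5
    baseline_mean: float = 1.0
    nb_dispersion_young: float = 0.5
    nb_dispersion_old_multiplier: float = 1.0
    noisy_types: list[str] | None = None  # None = dispersion multiplier hits all types
    lr_pairs: list[LRPlant] | None = None  # None = one pair of each delta class
    donors_per_group: int = 8
    donor_sigma: float = 0.1
    gene_mean_sigma: float = 0.4  # lognormal spread of per-gene baseline means
    plant_regulator: bool = False
    n_regulator_targets: int = 20
    regulator_strength: float = 1.0
    n_decoy_tfs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_pairs is None and self.n_cell_types >= 1:
            self.lr_pairs = _default_lr_pairs(self.n_cell_types)

    def validate(self) -> None:
        positive = {
            "n_cell_types": self.n_cell_types,
            "cells_per_type_per_group": self.cells_per_type_per_group,
            "n_genes": self.n_genes,
            "baseline_mean": self.baseline_mean,
            "donors_per_group": self.donors_per_group,
            "sasp_old_multiplier": self.sasp_old_multiplier,
        }
        for name, value in positive.items():
            if value <= 0:
                raise SimConfigError(f"{name} must be strictly positive, got {value}")
        for name, value in (
            ("n_markers_per_type", self.n_markers_per_type),
            ("n_aging_degs_per_type", self.n_aging_degs_per_type),
            ("sasp_set_size", self.sasp_set_size),
            ("nb_dispersion_young", self.nb_dispersion_young),
        ):
            if value < 0:
                raise SimConfigError(f"{name} must be >= 0, got {value}")
        if self.nb_dispersion_old_multiplier < 1:
            raise SimConfigError("nb_dispersion_old_multiplier must be >= 1")
        for pair in self.lr_pairs:
            if not (0 <= pair.sender < self.n_cell_types and 0 <= pair.receiver < self.n_cell_types):
                raise SimConfigError(f"LR pair references unknown cell type: {pair}")
        n_roles = self._n_role_genes()
        if n_roles > self.n_genes:
            raise SimConfigError(
                f"planted roles need {n_roles} distinct genes but the universe has "
                f"{self.n_genes}; roles would overlap, which is not allowed"
            )

    def _n_role_genes(self) -> int:
        n = (
            self.n_cell_types * self.n_markers_per_type
            + self.n_cell_types * self.n_aging_degs_per_type
            + self.sasp_set_size
            + 2 * len(self.lr_pairs)
        )
        if self.plant_regulator:
            n += 1 + self.n_regulator_targets + self.n_decoy_tfs
        return n

    def cell_type_names(self) -> list[str]:
        if self.n_cell_types == len(CANONICAL_TYPES):
            return list(CANONICAL_TYPES)
        return [f"CT{i + 1:02d}" for i in range(self.n_cell_types)]

    def layer_of(self, type_name: str, type_index: int) -> str:
        if type_name in CANONICAL_TYPES:
            return CANONICAL_TYPES[type_name]
        return "neural" if type_index < math.ceil(self.n_cell_types / 2) else "RPE-choroid"


@dataclass
class GroundTruth:
    true_markers: dict[str, list[str]]
    true_degs: dict[str, list[tuple[str, float]]]
    true_sasp_genes: list[str]
    true_sasp_shift: float
    true_interaction_classes: dict[tuple[str, str, str], str]
    type_labels: list[str]
    group_labels: list[str]
    noisy_types: list[str]
    regulator: dict | None = None
    expected_means: np.ndarray | None = None  # genes x types x {young, old}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_markers": self.true_markers,
            "true_degs": {t: [[g, f] for g, f in v] for t, v in self.true_degs.items()},
            "true_sasp_genes": self.true_sasp_genes,
            "true_sasp_shift": self.true_sasp_shift,
            "true_interaction_classes": [
                {"sender": s, "receiver": r, "pair": p, "class": c}
                for (s, r, p), c in self.true_interaction_classes.items()
            ],
            "type_labels": self.type_labels,
            "group_labels": self.group_labels,
            "noisy_types": self.noisy_types,
            "regulator": self.regulator,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mean + dispersion * mean**2."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def generate_atlas(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, GeneSetCollection, GroundTruth]:
    """Draw one synthetic atlas; identical (config, seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_cell_types
    types = config.cell_type_names()
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    # --- role assignment: disjoint gene slices from a shuffled universe -----
    order = rng.permutation(config.n_genes)
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        idx = order[cursor : cursor + n]
        cursor += n
        return idx.tolist()

    marker_idx = {t: take(config.n_markers_per_type) for t in types}
    deg_idx = {t: take(config.n_aging_degs_per_type) for t in types}
    sasp_idx = take(config.sasp_set_size)
    lr_idx = [(take(1)[0], take(1)[0]) for _ in config.lr_pairs]
    reg_tf_idx = reg_target_idx = decoy_tf_idx = None
    if config.plant_regulator:
        reg_tf_idx = take(1)[0]
        reg_target_idx = take(config.n_regulator_targets)
        decoy_tf_idx = take(config.n_decoy_tfs)

    # --- expected mean per (gene, type, group) ------------------------------
    base = config.baseline_mean * np.exp(
        rng.normal(0.0, config.gene_mean_sigma, size=config.n_genes)
        - config.gene_mean_sigma**2 / 2
    )
    regulon = [] if reg_tf_idx is None else [reg_tf_idx, *reg_target_idx]
    if regulon:
        base[regulon] = max(3.0, config.baseline_mean)
    means = np.repeat(base[:, None, None], k, axis=1).repeat(2, axis=2)  # young=0, old=1

    deg_signs: dict[str, list[float]] = {}
    for ti, t in enumerate(types):
        means[marker_idx[t], ti, :] *= 2.0**config.marker_log2fc
        signs = [1.0 if j % 2 == 0 else -1.0 for j in range(len(deg_idx[t]))]
        deg_signs[t] = [s * config.aging_log2fc for s in signs]
        for gi, lfc in zip(deg_idx[t], deg_signs[t]):
            means[gi, ti, 1] *= 2.0**lfc
    means[sasp_idx, :, 1] *= config.sasp_old_multiplier
    for (li, ri), pair in zip(lr_idx, config.lr_pairs):
        means[li, :, :] = LR_INACTIVE_MEAN
        means[ri, :, :] = LR_INACTIVE_MEAN
        for age_i, active in ((0, pair.active_young), (1, pair.active_old)):
            if active:
                means[li, pair.sender, age_i] = LR_ACTIVE_MEAN
                means[ri, pair.receiver, age_i] = LR_ACTIVE_MEAN

    # --- cells, donors, metadata -------------------------------------------
    n_cells = 2 * k * config.cells_per_type_per_group
    cell_type_labels, group_labels, donor_labels = [], [], []
    blocks = []  # (type index, group index, cell slice)
    start = 0
    for gi_group, group in enumerate(("young", "old")):
        prefix = "Y" if group == "young" else "O"
        donors = [f"{prefix}{d + 1}" for d in range(config.donors_per_group)]
        for ti, t in enumerate(types):
            n = config.cells_per_type_per_group
            cell_type_labels += [t] * n
            group_labels += [group] * n
            donor_labels += [donors[j % len(donors)] for j in range(n)]
            blocks.append((ti, gi_group, slice(start, start + n)))
            start += n
    cell_ids = [f"C{i + 1:05d}" for i in range(n_cells)]

    donor_names = sorted(set(donor_labels))
    donor_factors = {
        d: np.exp(
            rng.normal(0.0, config.donor_sigma, size=config.n_genes)
            - config.donor_sigma**2 / 2
        )
        if config.donor_sigma > 0
        else np.ones(config.n_genes)
        for d in donor_names
    }

    reg_activity = (
        np.exp(rng.normal(0.0, config.regulator_strength, size=n_cells))
        if config.plant_regulator
        else None
    )

    noisy = set(config.noisy_types) if config.noisy_types is not None else set(types)
    counts = np.zeros((config.n_genes, n_cells), dtype=np.int64)
    donor_arr = np.array(donor_labels)
    for ti, gi_group, cells in blocks:
        t = types[ti]
        phi = config.nb_dispersion_young
        if gi_group == 1 and t in noisy:
            phi *= config.nb_dispersion_old_multiplier
        mu_gene = means[:, ti, gi_group]
        block_donors = donor_arr[cells]
        mu = np.stack([mu_gene * donor_factors[d] for d in block_donors], axis=1)
        if reg_activity is not None:
            mu[regulon, :] = mu[regulon, :] * reg_activity[cells][None, :]
        counts[:, cells] = _nb_sample(rng, mu, phi)

    matrix = CountMatrix(sp.csr_matrix(counts), genes, cell_ids)
    sexes = {d: ("female" if int(d[1:]) % 2 == 0 else "male") for d in donor_names}
    metadata = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "donor": donor_labels,
            "age_group": group_labels,
            "sex": [sexes[d] for d in donor_labels],
            "layer": [
                config.layer_of(t, types.index(t)) for t in cell_type_labels
            ],
            "true_type": cell_type_labels,
        }
    )

    # --- gene sets (SASP + placeholder disease/aging sets + markers + TFs) --
    all_deg_genes = [genes[i] for t in types for i in deg_idx[t]]
    sets: dict[str, list[str]] = {}
    prov: dict[str, str] = {}
    if sasp_idx:
        sets["SASP"] = [genes[i] for i in sasp_idx]
        prov["SASP"] = "synthetic: planted senescence-associated secretory phenotype set"
    for name in ("GenAge", "AMD", "RP"):
        if all_deg_genes:
            pick = rng.choice(len(all_deg_genes), size=min(20, len(all_deg_genes)), replace=False)
            sets[name] = sorted({all_deg_genes[i] for i in pick})
            prov[name] = f"synthetic: placeholder {name} set sampled from planted aging DEGs"
    for t in types:
        if marker_idx[t]:
            sets[f"markers_{t}"] = [genes[i] for i in marker_idx[t]]
            prov[f"markers_{t}"] = "synthetic: planted cell-type markers"
    regulator = None
    if config.plant_regulator:
        tf = genes[reg_tf_idx]
        targets = [genes[i] for i in reg_target_idx]
        decoys = [genes[i] for i in decoy_tf_idx]
        sets["TF"] = sorted([tf, *decoys])
        prov["TF"] = "synthetic: planted regulator plus inert decoy TFs"
        regulator = {"tf": tf, "targets": targets, "decoy_tfs": decoys}
    genesets = GeneSetCollection(sets, prov)

    # --- ground truth -------------------------------------------------------
    null_aging = (
        config.n_aging_degs_per_type == 0
        and config.sasp_old_multiplier == 1.0
        and config.nb_dispersion_old_multiplier == 1.0
    )
    true_degs = (
        {t: [] for t in types}
        if null_aging
        else {
            t: [(genes[i], lfc) for i, lfc in zip(deg_idx[t], deg_signs[t])]
            for t in types
        }
    )
    classes = {}
    for (li, ri), pair in zip(lr_idx, config.lr_pairs):
        label = f"{genes[li]}-{genes[ri]}"
        key = (types[pair.sender], types[pair.receiver], label)
        if pair.active_old and not pair.active_young:
            classes[key] = "newborn"
        elif pair.active_young and not pair.active_old:
            classes[key] = "disappeared"
        elif pair.active_young and pair.active_old:
            classes[key] = "unchanged"
        else:
            classes[key] = "absent"
    truth = GroundTruth(
        true_markers={t: [genes[i] for i in marker_idx[t]] for t in types},
        true_degs=true_degs,
        true_sasp_genes=[genes[i] for i in sasp_idx],
        true_sasp_shift=config.sasp_old_multiplier,
        true_interaction_classes=classes,
        type_labels=cell_type_labels,
        group_labels=group_labels,
        noisy_types=sorted(noisy & set(types)) if config.nb_dispersion_old_multiplier > 1 else [],
        regulator=regulator,
        expected_means=means,
    )
    return matrix, metadata, genesets, truth


def lr_pair_table(genesets_truth: GroundTruth) -> pd.DataFrame:
    """Two-column ligand/receptor table derived from planted interactions."""
    rows = []
    for (_, _, label) in genesets_truth.true_interaction_classes:
        ligand, receptor = label.split("-")
        rows.append({"ligand": ligand, "receptor": receptor})
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)


def write_atlas(
    outdir: str | Path,
    counts: CountMatrix,
    metadata: pd.DataFrame,
    genesets: GeneSetCollection,
    truth: GroundTruth,
) -> None:
    """Serialize a generated atlas: MTX + TSVs + GMT + ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(counts, outdir, format="mtx")
    write_metadata(metadata, outdir / "metadata.tsv")
    write_gmt(genesets, outdir / "genesets.gmt")
    truth.to_json(outdir / "ground_truth.json")
    lr_pair_table(truth).to_csv(outdir / "lr_pairs.csv", index=False)
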