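"""Planted-truth benchmarks: every pipeline stage scored against ground truth.

Each function generates data with :mod:`retatlas.syndata`, runs the stage
under study through its public API, and measures recovery of the planted
signal (or calibration under the exchangeable null).  All randomness flows
from the ``seed`` argument.  These drive both the verification test suite
and the reported numbers in ``scripts/acceptance.py`` and ``analysis/``.
"""

from __future__ import annotations

import dataclasses
from math import comb

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .aging_de import RotsParams, call_degs
from .cluster_annotate import annotate_clusters, embed_cluster, select_hvgs
from .interactions import LRPair, active_interactions, classify_interactions
from .networks import enrich_terms, overlap_network, regulatory_network
from .qcnorm import normalize
from .scores import (
    GeneSetCollection,
    geneset_score,
    score_group_comparison,
    transcriptional_noise_cv,
)
from .syndata import SimConfig, generate_atlas

DEG_PARAMS = RotsParams(alpha1=0.1, alpha2=1.0)


def _sub_seed(seed: int, salt: int) -> int:
    return int(np.random.default_rng([seed, salt]).integers(2**31))


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def rots_null_calibration(
    seed: int, n_genes: int = 1000, cells_per_group: int = 50, n_permutation: int = 200
) -> dict:
    """Fraction of permutation p-values below 0.05 on exchangeable-null data."""
    cfg = SimConfig(
        n_cell_types=1, cells_per_type_per_group=cells_per_group, n_genes=n_genes,
        n_aging_degs_per_type=0, sasp_old_multiplier=1.0,
        nb_dispersion_old_multiplier=1.0, lr_pairs=[], seed=seed,
    )
    counts, meta, _, truth = generate_atlas(cfg)
    meta = meta.assign(cell_type=truth.type_labels)
    res = call_degs(
        normalize(counts), meta,
        params=dataclasses.replace(DEG_PARAMS, seed=_sub_seed(seed, 1)),
        n_permutation=n_permutation,
    )
    p = res.table.p.to_numpy()
    return {"frac_p_lt_05": float((p < 0.05).mean()), "n_genes": n_genes}


def deg_recovery(
    seed: int,
    n_seeds: int = 10,
    n_genes: int = 1000,
    cells_per_group: int = 50,
    frac_planted: float = 0.05,
    aging_log2fc: float = 2.0,
    n_permutation: int = 200,
) -> dict:
    """Sensitivity and empirical FDR for planted aging DEGs, seed-averaged."""
    sens, efdr = [], []
    n_planted = int(round(frac_planted * n_genes))
    for i in range(n_seeds):
        cfg = SimConfig(
            n_cell_types=1, cells_per_type_per_group=cells_per_group,
            n_genes=n_genes, n_aging_degs_per_type=n_planted,
            aging_log2fc=aging_log2fc, sasp_old_multiplier=1.0, lr_pairs=[],
            seed=_sub_seed(seed, 100 + i),
        )
        counts, meta, _, truth = generate_atlas(cfg)
        meta = meta.assign(cell_type=truth.type_labels)
        res = call_degs(
            normalize(counts), meta,
            params=dataclasses.replace(DEG_PARAMS, seed=_sub_seed(seed, 200 + i)),
            n_permutation=n_permutation,
        )
        truthg = {g for g, _ in truth.true_degs["CT01"]}
        called = set(res.table.loc[res.table.is_deg, "gene"])
        sens.append(len(called & truthg) / len(truthg))
        efdr.append(len(called - truthg) / max(len(called), 1))
    return {
        "sensitivity": float(np.mean(sens)),
        "empirical_fdr": float(np.mean(efdr)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# SASP score and CV noise
# ---------------------------------------------------------------------------

def sasp_recovery(
    seed: int,
    n_seeds: int = 100,
    multiplier: float = 2.0,
    cells_per_group: int = 500,
    n_genes: int = 150,
    p_threshold: float = 0.01,
) -> dict:
    """How often the old-cell SASP median exceeds young at Wilcoxon p < thr."""
    wins = 0
    medians = []
    for i in range(n_seeds):
        cfg = SimConfig(
            n_cell_types=1, cells_per_type_per_group=cells_per_group,
            n_genes=n_genes, sasp_set_size=30, sasp_old_multiplier=multiplier,
            n_aging_degs_per_type=0, lr_pairs=[], seed=_sub_seed(seed, 300 + i),
        )
        counts, meta, _, truth = generate_atlas(cfg)
        meta = meta.assign(cell_type=truth.type_labels)
        table = geneset_score(
            normalize(counts), GeneSetCollection({"SASP": truth.true_sasp_genes}), meta
        )
        comp = score_group_comparison(table).iloc[0]
        medians.append((comp.median_young, comp.median_old))
        if comp.median_old > comp.median_young and comp.p < p_threshold:
            wins += 1
    med = np.mean(medians, axis=0)
    return {
        "n_detected": wins,
        "n_seeds": n_seeds,
        "median_young": float(med[0]),
        "median_old": float(med[1]),
    }


def cv_noise_recovery(
    seed: int,
    n_seeds: int = 100,
    dispersion_multiplier: float = 2.0,
    cells_per_group: int = 40,
    n_genes: int = 200,
) -> dict:
    """Old-vs-young median CV in the noise-planted type and an untouched type."""
    affected_wins = unaffected_wins = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            n_cell_types=2, cells_per_type_per_group=cells_per_group,
            n_genes=n_genes, nb_dispersion_old_multiplier=dispersion_multiplier,
            noisy_types=["CT01"], n_aging_degs_per_type=0,
            sasp_old_multiplier=1.0, lr_pairs=[], seed=_sub_seed(seed, 400 + i),
        )
        counts, meta, _, truth = generate_atlas(cfg)
        meta = meta.assign(cell_type=truth.type_labels)
        _, _, comp = transcriptional_noise_cv(normalize(counts), meta)
        comp = comp.set_index("cell_type")
        if comp.loc["CT01", "median_cv_old"] > comp.loc["CT01", "median_cv_young"]:
            affected_wins += 1
        if comp.loc["CT02", "median_cv_old"] > comp.loc["CT02", "median_cv_young"]:
            unaffected_wins += 1
    return {
        "n_affected_detected": affected_wins,
        "n_unaffected_elevated": unaffected_wins,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def interaction_oracle_check(seed: int, n_trials: int = 500) -> dict:
    """classify_interactions vs plain set algebra on random activity sets."""
    rng = np.random.default_rng(seed)
    types = ["A", "B", "C", "D"]
    pairs = [f"L{i}-R{i}" for i in range(8)]
    universe = [(s, r, p) for s in types for r in types for p in pairs]
    mismatches = invariant_failures = 0
    for _ in range(n_trials):
        young = {universe[j] for j in rng.choice(len(universe), rng.integers(0, 50), replace=False)}
        old = {universe[j] for j in rng.choice(len(universe), rng.integers(0, 50), replace=False)}
        records, summary = classify_interactions(young, old)
        got = {
            cls: {(r.sender, r.receiver, r.pair) for r in records if r.delta_class == cls}
            for cls in ("newborn", "disappeared", "unchanged")
        }
        if (
            got["newborn"] != old - young
            or got["disappeared"] != young - old
            or got["unchanged"] != young & old
        ):
            mismatches += 1
        t = summary["totals"]
        if (
            t["n_young"] != t["n_unchanged"] + t["n_disappeared"]
            or t["n_old"] != t["n_unchanged"] + t["n_newborn"]
        ):
            invariant_failures += 1
    return {
        "n_trials": n_trials,
        "n_mismatches": mismatches,
        "n_invariant_failures": invariant_failures,
    }


def overlap_network_oracle_check(seed: int, n_tables: int = 100) -> dict:
    """Node/edge weights vs brute-force recomputation on random DEG tables."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(30)]
    types = ["T1", "T2", "T3", "T4"]
    mismatches = 0
    for _ in range(n_tables):
        rows = []
        seen = set()
        for _ in range(rng.integers(1, 40)):
            key = (types[rng.integers(4)], genes[rng.integers(30)])
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {
                    "cell_type": key[0], "gene": key[1],
                    "log2fc": float(rng.normal()), "d": 1.0, "p": 0.001,
                    "fdr": 0.001, "is_deg": True,
                }
            )
        degs = pd.DataFrame(rows)
        degs["direction"] = np.where(degs.log2fc > 0, "up", "down")
        set_genes = sorted(rng.choice(genes, rng.integers(1, 15), replace=False))
        direction = "up" if rng.random() < 0.5 else "down"
        net = overlap_network(degs, GeneSetCollection({"S": set_genes}), direction)
        expected: dict[str, list[float]] = {}
        for r in degs.itertuples():
            if r.direction == direction and r.gene in set_genes:
                expected.setdefault(r.gene, []).append(r.log2fc)
        ok = set(net.nodes.gene) == set(expected)
        if ok:
            nodes = net.nodes.set_index("gene")
            for g, fcs in expected.items():
                if nodes.loc[g, "n_cell_types"] != len(fcs) or not np.isclose(
                    nodes.loc[g, "mean_log2fc"], np.mean(fcs)
                ):
                    ok = False
        if not ok:
            mismatches += 1
    return {"n_tables": n_tables, "n_mismatches": mismatches}


def hypergeometric_oracle_check(max_universe: int = 20) -> dict:
    """enrich_terms vs the exact binomial-coefficient tail sum, N <= 20."""
    worst = 0.0
    n_checked = 0
    for N in range(4, max_universe + 1):
        universe = [f"g{i}" for i in range(N)]
        for K in range(1, N + 1):
            term = universe[:K]
            for n in range(1, N + 1):
                for k in range(max(0, K + n - N), min(K, n) + 1):
                    gene_list = term[:k] + universe[K : K + (n - k)]
                    if len(gene_list) != n:
                        continue
                    p = enrich_terms(gene_list, {"T": term}, universe).p.iloc[0]
                    exact = sum(
                        comb(K, i) * comb(N - K, n - i) / comb(N, n)
                        for i in range(k, min(K, n) + 1)
                    )
                    worst = max(worst, abs(p - exact))
                    n_checked += 1
    return {"n_instances": n_checked, "max_abs_error": float(worst)}


# ---------------------------------------------------------------------------
# clustering / annotation and regulators
# ---------------------------------------------------------------------------

def clustering_recovery(seed: int, config: SimConfig | None = None) -> dict:
    """ARI and marker-reference annotation accuracy on the default atlas."""
    cfg = config or SimConfig(seed=_sub_seed(seed, 500))
    counts, meta, _, truth = generate_atlas(cfg)
    expr = normalize(counts)
    hvgs = select_hvgs(expr, min(2000, len(expr.gene_ids)))
    result = embed_cluster(expr, hvgs, cfg.n_cell_types, seed=_sub_seed(seed, 501))
    ari = adjusted_rand_score(truth.type_labels, result.labels)
    mapping = annotate_clusters(expr, result.labels, truth.true_markers)
    majority = (
        pd.DataFrame({"cluster": result.labels, "true": truth.type_labels})
        .groupby("cluster")["true"]
        .agg(lambda s: s.mode()[0])
    )
    n_correct = sum(mapping[c] == majority[c] for c in majority.index)
    return {
        "ari": float(ari),
        "n_types": cfg.n_cell_types,
        "n_clusters_correctly_annotated": int(n_correct),
    }


def regulator_recovery(
    seed: int, n_seeds: int = 100, n_targets: int = 20
) -> dict:
    """How often the planted TF ranks first by connection count."""
    # the gene universe is kept large enough (600) that the 21-gene regulon
    # stays a small fraction of each cell's transcriptome; otherwise depth
    # normalization divides out the shared activity factor and attenuates
    # the planted co-expression
    first = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            n_cell_types=1, cells_per_type_per_group=60, n_genes=600,
            n_markers_per_type=0, n_aging_degs_per_type=0,
            sasp_old_multiplier=1.0, lr_pairs=[], plant_regulator=True,
            n_regulator_targets=n_targets, seed=_sub_seed(seed, 600 + i),
        )
        counts, meta, sets, truth = generate_atlas(cfg)
        meta = meta.assign(cell_type=truth.type_labels)
        reg = truth.regulator
        deg_genes = [reg["tf"], *reg["targets"], *reg["decoy_tfs"]]
        net = regulatory_network(
            normalize(counts), meta, "CT01", deg_genes, sets["TF"]
        )
        if net.top_regulators and net.top_regulators[0] == reg["tf"]:
            first += 1
    return {"n_rank_first": first, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# interactions end to end
# ---------------------------------------------------------------------------

def interaction_recovery(seed: int) -> dict:
    """Planted LR activity patterns recovered through the expression route."""
    cfg = SimConfig(
        n_cell_types=3, cells_per_type_per_group=40, n_genes=400,
        n_aging_degs_per_type=0, sasp_old_multiplier=1.0,
        seed=_sub_seed(seed, 700),
    )
    counts, meta, _, truth = generate_atlas(cfg)
    meta = meta.assign(cell_type=truth.type_labels)
    expr = normalize(counts)
    lr_db = [LRPair(*p.split("-")) for (_, _, p) in truth.true_interaction_classes]
    young = active_interactions(expr, meta, lr_db, "young")
    old = active_interactions(expr, meta, lr_db, "old")
    records, summary = classify_interactions(young, old)
    found = {(r.sender, r.receiver, r.pair): r.delta_class for r in records}
    correct = sum(
        found.get(k, "absent") == v for k, v in truth.true_interaction_classes.items()
    )
    out = {"n_planted": len(truth.true_interaction_classes), "n_correct": correct}
    out.update(summary["totals"])
    return out
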