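"""One-config, one-seed orchestration of the full atlas analysis.

Stage order: simulate (or read external counts) -> qc -> cluster/annotate ->
aging DEGs -> gene-set scores & CV noise -> ligand-receptor interactions ->
networks.  Every stage writes its artifacts under the output directory and a
manifest JSON records files, config hash, seed and package version, so an
identical (config, seed) run reproduces the manifest hash byte-for-byte.
Per-stage sub-seeds are derived as hash(global seed, stage name) so adding a
stage does not shift the randomness of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aging_de import RotsParams, call_degs
from .cluster_annotate import annotate_clusters, embed_cluster, rank_markers, select_hvgs
from .interactions import (
    LRPair,
    active_interactions,
    classify_interactions,
    read_lr_pairs,
    records_to_frame,
)
from .networks import enrich_terms, overlap_network, regulatory_network
from .qcnorm import (
    CountMatrix,
    QCThresholds,
    filter_cells,
    normalize,
    read_counts,
    read_metadata,
    write_counts,
    write_metadata,
)
from .scores import (
    GeneSetCollection,
    geneset_score,
    read_gmt,
    score_group_comparison,
    transcriptional_noise_cv,
)
from .syndata import LRPlant, SimConfig, generate_atlas, lr_pair_table, write_atlas

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "cluster", "deg", "scores", "interactions", "networks")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    synthetic: SimConfig | None = None
    counts_path: str | None = None
    counts_format: str = "mtx"
    metadata_path: str | None = None
    qc: QCThresholds = field(default_factory=lambda: QCThresholds(100, 200, 3))
    scale: float = 1e4
    n_clusters: int | None = None
    n_hvgs: int = 2000
    n_components: int = 20
    annotation_reference: str | None = None  # GMT of reference markers, or None
    deg_params: RotsParams | str = "auto"
    deg_n_permutation: int = 200
    deg_min_cells: int = 10
    fdr_threshold: float = 0.05
    genesets_path: str | None = None
    lr_path: str | None = None
    min_frac: float = 0.1
    min_mean: float = 0.1
    min_abs_corr: float = 0.3
    regulatory_cell_type: str | None = None
    regulatory_direction: str = "down"
    seed: int = 0

    def validate(self) -> None:
        has_synth = self.synthetic is not None
        has_paths = self.counts_path is not None
        if has_synth == has_paths:
            raise ConfigError("exactly one input source: 'synthetic' or 'counts_path'")
        if has_paths and self.metadata_path is None:
            raise ConfigError("external counts require 'metadata_path'")
        for label, p in (
            ("counts_path", self.counts_path),
            ("metadata_path", self.metadata_path),
            ("genesets_path", self.genesets_path),
            ("lr_path", self.lr_path),
            ("annotation_reference", self.annotation_reference),
        ):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label} does not exist: {p}")
        if has_synth:
            self.synthetic.validate()
        if self.regulatory_direction not in ("up", "down"):
            raise ConfigError("regulatory_direction must be 'up' or 'down'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.deg_params, RotsParams):
            d["deg_params"] = dataclasses.asdict(self.deg_params)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            synth = dict(raw["synthetic"])
            if "lr_pairs" in synth:
                synth["lr_pairs"] = [LRPlant(**p) for p in synth["lr_pairs"]]
            kwargs["synthetic"] = SimConfig(**synth)
        if "qc" in raw and raw["qc"] is not None:
            kwargs["qc"] = QCThresholds(**raw["qc"])
        if isinstance(raw.get("deg_params"), dict):
            kwargs["deg_params"] = RotsParams(**raw["deg_params"])
        elif "deg_params" in raw:
            kwargs["deg_params"] = raw["deg_params"]
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key in ("synthetic", "qc", "deg_params"):
                continue
            if key not in known:
                raise ConfigError(f"unknown config key {key!r}")
            kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


class PipelineState:
    """In-memory artifacts shared between stages; reloadable from disk."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.counts: CountMatrix | None = None
        self.metadata: pd.DataFrame | None = None
        self.genesets: GeneSetCollection | None = None
        self.expr = None
        self.deg_table: pd.DataFrame | None = None

    def require_qc(self, cfg: PipelineConfig):
        if self.counts is None:
            qcdir = self.outdir / "qc"
            if not (qcdir / "matrix.mtx").exists():
                raise FileNotFoundError("run the 'qc' stage first")
            self.counts = read_counts(qcdir, format="mtx")
            self.metadata = read_metadata(self.outdir / "metadata_annotated.tsv") if (
                self.outdir / "metadata_annotated.tsv"
            ).exists() else read_metadata(qcdir / "metadata.tsv")
        if self.expr is None:
            self.expr = normalize(self.counts, scale=cfg.scale)

    def require_genesets(self, cfg: PipelineConfig) -> GeneSetCollection:
        if self.genesets is None:
            path = cfg.genesets_path or (self.outdir / "raw" / "genesets.gmt")
            if not Path(path).exists():
                raise FileNotFoundError(f"no gene sets at {path}")
            self.genesets = read_gmt(path)
        return self.genesets

    def require_degs(self) -> pd.DataFrame:
        if self.deg_table is None:
            path = self.outdir / "deg" / "deg_table.csv"
            if not path.exists():
                raise FileNotFoundError("run the 'deg' stage first")
            self.deg_table = pd.read_csv(path)
        return self.deg_table


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, state: PipelineState, seed: int) -> None:
    if cfg.synthetic is not None:
        sim = dataclasses.replace(cfg.synthetic, seed=derive_seed(seed, "simulate"))
        counts, meta, sets, truth = generate_atlas(sim)
        write_atlas(state.outdir / "raw", counts, meta, sets, truth)
        state.genesets = sets if cfg.genesets_path is None else None
    else:
        counts = read_counts(cfg.counts_path, format=cfg.counts_format)
        meta = read_metadata(cfg.metadata_path)
        (state.outdir / "raw").mkdir(parents=True, exist_ok=True)
        write_counts(counts, state.outdir / "raw", format="mtx")
        write_metadata(meta, state.outdir / "raw" / "metadata.tsv")
    state.counts, state.metadata = counts, meta


def _stage_qc(cfg: PipelineConfig, state: PipelineState, seed: int) -> None:
    if state.counts is None:
        state.counts = read_counts(state.outdir / "raw", format="mtx")
        state.metadata = read_metadata(state.outdir / "raw" / "metadata.tsv")
    filtered, report = filter_cells(state.counts, cfg.qc)
    qcdir = state.outdir / "qc"
    write_counts(filtered, qcdir, format="mtx")
    report.to_json(qcdir / "qc_report.json")
    kept = state.metadata[state.metadata["cell_id"].isin(filtered.cell_ids)]
    write_metadata(kept, qcdir / "metadata.tsv")
    state.counts, state.metadata, state.expr = filtered, kept.reset_index(drop=True), None


def _stage_cluster(cfg: PipelineConfig, state: PipelineState, seed: int) -> None:
    state.require_qc(cfg)
    n_clusters = cfg.n_clusters or (
        cfg.synthetic.n_cell_types if cfg.synthetic else None
    )
    if n_clusters is None:
        raise ConfigError("n_clusters must be set for external inputs")
    hvgs = select_hvgs(state.expr, min(cfg.n_hvgs, len(state.expr.gene_ids)))
    result = embed_cluster(
        state.expr, hvgs, n_clusters, seed=derive_seed(seed, "cluster"),
        n_components=cfg.n_components,
    )
    markers = rank_markers(state.expr, result.labels, top_n=100)
    reference = _reference_markers(cfg, state)
    if reference:
        mapping = annotate_clusters(state.expr, result.labels, reference)
        cell_type = [str(mapping[c]) for c in result.labels]
    else:
        cell_type = [f"cluster{c}" for c in result.labels]
        mapping = {}
    meta = state.metadata.copy()
    meta["cluster"] = result.labels
    meta["cell_type"] = cell_type
    write_metadata(meta, state.outdir / "metadata_annotated.tsv")
    cdir = state.outdir / "cluster"
    cdir.mkdir(parents=True, exist_ok=True)
    markers.to_csv(cdir / "markers.csv", index=False)
    (cdir / "annotation.json").write_text(
        json.dumps({str(k): v for k, v in mapping.items()}, indent=1, sort_keys=True)
    )
    state.metadata = meta


def _reference_markers(cfg: PipelineConfig, state: PipelineState) -> dict[str, list[str]]:
    if cfg.annotation_reference:
        sets = read_gmt(cfg.annotation_reference)
        return {name: sets[name] for name in sets.names()}
    try:
        sets = state.require_genesets(cfg)
    except FileNotFoundError:
        return {}
    return {
        name.removeprefix("markers_"): sets[name]
        for name in sets.names()
        if name.startswith("markers_")
    }


def _stage_deg(cfg: PipelineConfig, state: PipelineState, seed: int) -> None:
    state.require_qc(cfg)
    params = cfg.deg_params
    if isinstance(params, RotsParams):
        params = dataclasses.replace(params, seed=derive_seed(seed, "deg"))
    else:
        params = "auto"
    result = call_degs(
        state.expr,
        state.metadata,
        params=params if params != "auto" else "auto",
        min_cells=cfg.deg_min_cells,
        fdr_threshold=cfg.fdr_threshold,
        n_permutation=cfg.deg_n_permutation,
    )
    degdir = state.outdir / "deg"
    degdir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(degdir / "deg_table.csv", index=False)
    sidecar = {
        "skipped": result.skipped,
        "params_by_type": {
            t: dataclasses.asdict(p) for t, p in result.params_by_type.items()
        },
        "n_permutation": cfg.deg_n_permutation,
        "fdr_threshold": cfg.fdr_threshold,
    }
    (degdir / "deg_params.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    state.deg_table = result.table


def _stage_scores(cfg: PipelineConfig, state: PipelineState, seed: int) -> None:
    state.require_qc(cfg)
    sets = state.require_genesets(cfg)
    score_sets = GeneSetCollection(
        {n: sets[n] for n in sets.names() if not n.startswith(("markers_", "TF"))},
        {n: sets.provenance[n] for n in sets.names() if not n.startswith(("markers_", "TF"))},
    )
    scoredir = state.outdir / "scores"
    scoredir.mkdir(parents=True, exist_ok=True)
    table = geneset_score(state.expr, score_sets, state.metadata)
    table.to_csv(scoredir / "cell_scores.csv", index=False)
    score_group_comparison(table).to_csv(scoredir / "score_comparison.csv", index=False)
    score_group_comparison(table, stratify="cell_type").to_csv(
        scoredir / "score_comparison_by_type.csv", index=False
    )
    cv_table, cv_summary, cv_comp = transcriptional_noise_cv(state.expr, state.metadata)
    cv_table.to_csv(scoredir / "cv_table.csv", index=False)
    cv_summary.to_csv(scoredir / "cv_summary.csv", index=False)
    cv_comp.to_csv(scoredir / "cv_comparison.csv", index=False)


def _stage_interactions(cfg: PipelineConfig, state: PipelineState, seed: int) -> None:
    state.require_qc(cfg)
    lr_path = cfg.lr_path or (state.outdir / "raw" / "lr_pairs.csv")
    if not Path(lr_path).exists():
        raise FileNotFoundError(f"no LR database at {lr_path}")
    lr_db = read_lr_pairs(lr_path)
    kwargs = dict(min_frac=cfg.min_frac, min_mean=cfg.min_mean)
    young = active_interactions(state.expr, state.metadata, lr_db, "young", **kwargs)
    old = active_interactions(state.expr, state.metadata, lr_db, "old", **kwargs)
    records, summary = classify_interactions(young, old)
    idir = state.outdir / "interactions"
    idir.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(idir / "records.csv", index=False)
    serializable = {
        "totals": summary["totals"],
        "per_pair": {f"{s}->{r}": v for (s, r), v in sorted(summary["per_pair"].items())},
        "per_type": dict(sorted(summary["per_type"].items())),
        "thresholds": kwargs,
    }
    (idir / "summary.json").write_text(json.dumps(serializable, indent=1, sort_keys=True))


def _stage_networks(cfg: PipelineConfig, state: PipelineState, seed: int) -> None:
    state.require_qc(cfg)
    degs = state.require_degs()
    sets = state.require_genesets(cfg)
    overlap_sets = GeneSetCollection(
        {n: sets[n] for n in sets.names() if n in ("GenAge", "AMD", "RP", "SASP")}
        or {n: sets[n] for n in sets.names()},
    )
    ndir = state.outdir / "networks"
    ndir.mkdir(parents=True, exist_ok=True)
    for direction in ("up", "down"):
        try:
            net = overlap_network(degs, overlap_sets, direction)
        except ValueError:
            continue
        net.write(ndir / f"overlap_{direction}")
    focal = cfg.regulatory_cell_type or _default_focal_type(degs)
    if focal is not None:
        focal_degs = degs[
            (degs["cell_type"] == focal)
            & degs["is_deg"]
            & (degs["direction"] == cfg.regulatory_direction)
        ]["gene"].tolist()
        if focal_degs:
            enrich_terms(
                focal_degs, overlap_sets.sets, list(degs["gene"].unique())
            ).to_csv(ndir / f"enrichment_{focal}_{cfg.regulatory_direction}.csv", index=False)
            tf_list = sets["TF"] if "TF" in sets else focal_degs
            regnet = regulatory_network(
                state.expr, state.metadata, focal, focal_degs, tf_list,
                min_abs_corr=cfg.min_abs_corr,
            )
            regnet.write(ndir / f"regulatory_{focal}")


def _default_focal_type(degs: pd.DataFrame) -> str | None:
    called = degs[degs["is_deg"]]
    if called.empty:
        return None
    return called.groupby("cell_type").size().sort_index().idxmax()


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "deg": _stage_deg,
    "scores": _stage_scores,
    "interactions": _stage_interactions,
    "networks": _stage_networks,
}


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Execute the requested stages (default: all) and write a manifest.

    Returns the manifest dict.  A stage failure writes a partial manifest
    with status "failed" and raises :class:`StageError`.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    state = PipelineState(outdir)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "version": __version__,
        "stages": [],
        "status": "ok",
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, state, seed)
        except Exception as exc:
            manifest["status"] = "failed"
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            _write_manifest(manifest, outdir)
            raise StageError(stage, exc) from exc
        manifest["stages"].append(stage)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    files = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json" and path.suffix != ".log":
            files[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    manifest["files"] = files
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
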