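"""End-to-end orchestration: config -> simulate/load -> report tables.

A run executes, in order: (optional) synthetic data generation or file
loading, differential expression for every configured contrast,
signature standardization, gene-set enrichment of every signature,
two-stage immune annotation at levels 1-4, co-expression module
detection and merging, module-trait association against cytokine
deltas, and robust cytokine regression. Every output table is a
tab-delimited file; a JSON provenance record carries the config hash,
seed and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import ConfigError, ContrastSpec, GROUPS, SimulationConfig
from . import annotation as ann
from . import coexpression as coex
from . import cytokines as cyto
from . import diffexpr
from . import enrichment as enr
from . import io as eio
from .synthetic import (
    ANNOTATION_LEVELS,
    generate_cytokines,
    generate_expression,
    generate_gene_sets,
)

logger = logging.getLogger(__name__)


def default_contrasts() -> list:
    """The study's three comparison families over AC/BET/BER:
    between-group per condition, within-group EW vs M, and the
    difference-of-differences interactions (12 contrasts, 24 signatures
    with both directions)."""
    contrasts = []
    pairs = [("BER", "AC"), ("BET", "AC"), ("BER", "BET")]
    for cond in ("EW", "M"):
        for a, b in pairs:
            contrasts.append(ContrastSpec("between_group_within_condition", a, b, cond))
    for g in GROUPS:
        contrasts.append(ContrastSpec("within_group_EW_vs_M", g))
    for a, b in pairs:
        contrasts.append(ContrastSpec("difference_of_differences", a, b))
    return contrasts


@dataclass
class PipelineConfig:
    """Everything a run needs; either a simulation block or data paths."""

    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    annotation_path: str | None = None
    cytokine_path: str | None = None
    contrasts: list = field(default_factory=default_contrasts)
    first_stage_fdr: float = 0.01
    n_significant: int = 500
    n_top: int = 200
    beta: float = 7.0
    min_module_size: int = 50
    merge_cutoff: float = 0.29
    cytokine_offset: float = 1.0
    reporting_fdr: float = 0.05
    run_coexpression: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("first_stage_fdr", "n_significant", "n_top", "beta",
                     "min_module_size", "merge_cutoff", "cytokine_offset",
                     "reporting_fdr"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.simulation is None and not (self.expression_path and self.metadata_path):
            raise ConfigError("config needs a simulation block or data paths")

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["contrasts"] = [c.contrast_id for c in self.contrasts]
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path, seed: int | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; ``seed`` overrides the
    file's seed (and the simulation block's)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = None
    if "simulation" in raw:
        sim = SimulationConfig(**(raw["simulation"] or {}))
    contrasts = default_contrasts()
    if "contrasts" in raw:
        contrasts = [ContrastSpec(**c) for c in raw["contrasts"]]
    cfg = PipelineConfig(
        simulation=sim,
        contrasts=contrasts,
        **{k: v for k, v in raw.items() if k not in ("simulation", "contrasts")},
    )
    if seed is not None:
        cfg.seed = seed
    if cfg.simulation is not None:
        cfg.simulation.seed = cfg.seed
    return cfg


@dataclass
class RunReport:
    """All result tables of one run plus provenance."""

    tables: dict  # name -> DataFrame
    signatures: list
    provenance: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        sig_rows = [
            {"signature_id": s.signature_id, "contrast_id": s.contrast_id,
             "direction": s.direction, "rank": i + 1, "gene_id": g}
            for s in self.signatures
            for i, g in enumerate(s.gene_ids)
        ]
        pd.DataFrame(sig_rows).to_csv(out / "signatures.tsv", sep="\t", index=False)
        with open(out / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = config.simulation
        expr, samples, truth = generate_expression(sim)
        collection, maps = generate_gene_sets(sim, truth)
        cytokine_table = generate_cytokines(sim)
        return expr, samples, collection, maps, cytokine_table
    expr = eio.read_expression(config.expression_path)
    samples = eio.read_metadata(config.metadata_path)
    collection = eio.read_gmt(config.gmt_path) if config.gmt_path else None
    maps = eio.read_annotation(config.annotation_path) if config.annotation_path else {}
    cytokine_table = (
        eio.read_cytokines(config.cytokine_path) if config.cytokine_path else None
    )
    return expr, samples, collection, maps, cytokine_table


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    tables: dict = {}
    notes: list = []

    current = {"stage": "start"}

    def stage(name):
        current["stage"] = name
        logger.info("pipeline stage: %s", name)

    try:
        stage("inputs")
        expr, samples, collection, annotation_maps, cytokine_table = _load_inputs(config)
        universe = list(expr.index)

        stage("differential expression")
        deg_frames = []
        signatures = []
        for contrast in config.contrasts:
            deg = diffexpr.fit_contrast(expr, samples, contrast)
            deg_frames.append(deg)
            for direction in ("up", "down"):
                sig = diffexpr.standardize_signature(
                    deg, direction,
                    n_significant=config.n_significant, n_top=config.n_top,
                )
                if sig.gene_ids:
                    signatures.append(sig)
        tables["deg"] = pd.concat(deg_frames, ignore_index=True)

        if collection is not None:
            stage("enrichment")
            enrich_frames = [
                enr.enrich_collection(sig, collection, universe) for sig in signatures
            ]
            tables["enrichment"] = pd.concat(enrich_frames, ignore_index=True)

            stage("immune annotation")
            score_frames = []
            for sig in signatures:
                for level in sorted(annotation_maps):
                    scores = ann.run_level(
                        sig, collection, annotation_maps[level], universe,
                        fdr_threshold=config.first_stage_fdr,
                    )
                    if len(scores):
                        scores.insert(0, "query_id", sig.signature_id)
                        score_frames.append(scores)
            tables["immune_annotation"] = (
                pd.concat(score_frames, ignore_index=True)
                if score_frames
                else pd.DataFrame(columns=["query_id"] + ann.SCORE_COLUMNS)
            )
        else:
            notes.append("enrichment skipped: no gene-set collection configured")

        if config.run_coexpression:
            stage("coexpression")
            adjacency = coex.soft_adjacency(expr, beta=config.beta)
            tom = coex.topological_overlap(adjacency)
            partition = coex.detect_modules(1.0 - tom,
                                            min_module_size=config.min_module_size)
            partition = coex.merge_modules(expr, partition,
                                           cutoff=config.merge_cutoff)
            tables["modules"] = (
                partition.assignment.rename("module_label")
                .rename_axis("gene_id")
                .reset_index()
            )
            if partition.module_labels():
                eig = coex.eigengene_matrix(expr, partition)
                tables["eigengenes"] = eig.reset_index(names="module")
                if collection is not None and signatures:
                    tables["module_signature_enrichment"] = (
                        enr.module_signature_enrichment(partition, signatures, universe)
                    )
                if cytokine_table is not None:
                    deltas = cyto.compute_delta(cytokine_table)
                    deltas["y"] = cyto.log10_transform_delta(
                        deltas["delta"].to_numpy(), offset=config.cytokine_offset
                    )
                    traits = deltas.pivot_table(
                        index="cytokine", columns="subject_id", values="y"
                    )
                    eig_deltas = coex.eigengene_subject_deltas(eig, samples)
                    tables["module_cytokine_association"] = (
                        coex.module_trait_association(eig_deltas, traits)
                    )
            else:
                notes.append("no co-expression modules detected")
        else:
            notes.append("coexpression skipped by config")

        if cytokine_table is not None:
            stage("cytokine regression")
            tables["cytokine_fits"] = cyto.fit_cytokine_responses(
                cytokine_table, offset=config.cytokine_offset
            )
        else:
            notes.append("cytokine section skipped: no cytokine input")
    except Exception as exc:  # annotate failures with the stage
        raise RuntimeError(
            f"pipeline failed at stage {current['stage']!r}: {exc}"
        ) from exc

    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "notes": notes,
        "thresholds": {
            "first_stage_fdr": config.first_stage_fdr,
            "n_significant": config.n_significant,
            "n_top": config.n_top,
            "beta": config.beta,
            "min_module_size": config.min_module_size,
            "merge_cutoff": config.merge_cutoff,
            "reporting_fdr": config.reporting_fdr,
        },
    }
    return RunReport(tables=tables, signatures=signatures, provenance=provenance)
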