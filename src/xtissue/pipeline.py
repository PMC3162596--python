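"""End-to-end pipeline driver.

Stages, in order: quantify (counts → RPKM) → collapse (transcripts →
clusters) → enrich (tissue-enrichment selection) → project (homolog ids)
→ ontology (term over-representation) → gsea (preranked set enrichment
and/or the cross-species NES matrix).  Every stage writes its table under
the output directory and a run manifest records the seed, thresholds,
input checksums and per-stage record counts.  A failing stage aborts the
run with the stage name and cause.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as xio
from .enrichment import enrichment_tests, select_enriched
from .errors import XTissueError
from .gsea import cross_species_matrix, gsea_preranked, rank_by_neglog_p
from .homology import collapse_to_clusters, project_ids
from .ontology import energy_distribution, term_enrichment
from .quantify import quantify_counts

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("quantify", "collapse", "enrich", "project", "ontology", "gsea")


class PipelineError(XTissueError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Paths and thresholds driving one pipeline run."""

    counts: dict[str, str]  # tissue label -> counts TSV path
    target_tissue: str
    outdir: str
    homologs: str | None = None
    annotations: str | None = None
    gene_sets: str | None = None  # GMT; enables preranked GSEA
    target_matrix: str | None = None  # second-species matrix; enables compare
    alpha: float = 0.025
    rpkm_min: float = 10.0
    fdr_cutoff: float = 0.01
    pathway_p_cutoff: float = 0.05
    n_perm: int = 1000
    min_set_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "rpkm_min", "fdr_cutoff", "pathway_p_cutoff"):
            if getattr(self, name) <= 0:
                raise XTissueError(f"threshold {name} must be positive")
        if self.n_perm < 1:
            raise XTissueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise XTissueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "rpkm_min": config.rpkm_min,
            "fdr_cutoff": config.fdr_cutoff,
            "pathway_p_cutoff": config.pathway_p_cutoff,
            "n_perm": config.n_perm,
        },
        "inputs": {},
        "stages": [],
        "records": {},
    }

    def checksum_input(label: str, path: str | None) -> None:
        if path is not None:
            manifest["inputs"][label] = _sha256(path)

    def run_stage(stage: str, fn):
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(stage, exc) from exc
        manifest["stages"].append(stage)

    quants: dict[str, pd.DataFrame] = {}

    def stage_quantify() -> None:
        for tissue, path in config.counts.items():
            checksum_input(f"counts:{tissue}", path)
            counts = xio.read_counts_table(path)
            q = quantify_counts(counts, total_mapped="auto")
            xio.write_table(q, outdir / f"quant_{tissue}.tsv")
            quants[tissue] = q
        manifest["records"]["quantified_transcripts"] = {
            t: int(len(q)) for t, q in quants.items()
        }

    matrix_holder: dict[str, pd.DataFrame] = {}

    def stage_collapse() -> None:
        cols = {t: collapse_to_clusters(q) for t, q in quants.items()}
        matrix = pd.DataFrame(cols).fillna(0.0)
        matrix.index.name = "cluster"
        xio.write_expression_matrix(matrix, outdir / "matrix.tsv")
        matrix_holder["matrix"] = matrix
        manifest["records"]["clusters"] = int(len(matrix))

    enriched_holder: dict[str, object] = {}

    def stage_enrich() -> None:
        matrix = matrix_holder["matrix"]
        result = select_enriched(
            matrix, config.target_tissue, alpha=config.alpha, rpkm_min=config.rpkm_min
        )
        xio.write_table(result.records, outdir / f"enriched_{config.target_tissue}.tsv")
        enriched_holder["selection"] = result
        enriched_holder["tests"] = enrichment_tests(matrix, config.target_tissue)
        manifest["records"]["enriched_genes"] = int(len(result.records))

    def stage_project() -> None:
        if config.homologs is None:
            manifest["records"]["projected_genes"] = None
            return
        checksum_input("homologs", config.homologs)
        hmap = xio.parse_mapping_table(config.homologs, kind="homology")
        projected = project_ids(enriched_holder["selection"].records["cluster"], hmap)
        xio.write_table(
            pd.DataFrame({"cluster": projected}), outdir / "projected.tsv"
        )
        enriched_holder["projected"] = projected
        manifest["records"]["projected_genes"] = len(projected)

    def stage_ontology() -> None:
        if config.annotations is None:
            manifest["records"]["ontology_terms_tested"] = None
            return
        checksum_input("annotations", config.annotations)
        anns = xio.parse_mapping_table(config.annotations, kind="annotation")
        matrix = matrix_holder["matrix"]
        selection = enriched_holder["selection"]
        table = term_enrichment(
            selection.records["cluster"], matrix.index, anns, method="hypergeometric"
        )
        xio.write_table(table, outdir / "term_enrichment.tsv")
        energy = energy_distribution(matrix[config.target_tissue], anns)
        xio.write_table(energy, outdir / "energy_distribution.tsv")
        manifest["records"]["ontology_terms_tested"] = int(len(table))
        manifest["records"]["ontology_terms_significant"] = int(
            (table["q"] < config.fdr_cutoff).sum()
        )

    def stage_gsea() -> None:
        did_anything = False
        if config.gene_sets is not None:
            checksum_input("gene_sets", config.gene_sets)
            sets = xio.parse_gene_sets_gmt(config.gene_sets)
            ranked = rank_by_neglog_p(enriched_holder["tests"])
            results = gsea_preranked(
                ranked,
                sets,
                n_perm=config.n_perm,
                seed=config.seed,
                min_size=config.min_set_size,
            )
            tbl = pd.DataFrame(
                {
                    "set": [r.gene_set for r in results],
                    "size": [r.size for r in results],
                    "ES": [r.es for r in results],
                    "NES": [r.nes for r in results],
                    "NP": [r.nominal_p for r in results],
                    "FDR": [r.fdr_q for r in results],
                    "leading_edge": [";".join(sorted(r.leading_edge)) for r in results],
                }
            ).sort_values("NES", ascending=False, kind="mergesort")
            xio.write_table(tbl, outdir / "gsea_preranked.tsv")
            manifest["records"]["gsea_sets"] = int(len(tbl))
            did_anything = True
        if config.target_matrix is not None:
            checksum_input("target_matrix", config.target_matrix)
            targets = xio.read_expression_matrix(config.target_matrix)
            if config.homologs is None:
                raise XTissueError("cross-species comparison requires a homolog map")
            hmap = xio.parse_mapping_table(config.homologs, kind="homology")
            matrix = matrix_holder["matrix"]
            enriched_sets = {}
            for tissue in matrix.columns:
                sel = select_enriched(
                    matrix, tissue, alpha=config.alpha, rpkm_min=config.rpkm_min
                )
                enriched_sets[tissue] = project_ids(sel.records["cluster"], hmap)
            nes_matrix = cross_species_matrix(
                enriched_sets,
                targets,
                n_perm=config.n_perm,
                seed=config.seed,
                min_size=config.min_set_size,
            )
            xio.write_expression_matrix(nes_matrix.nes, outdir / "nes_matrix.tsv")
            xio.write_expression_matrix(nes_matrix.fdr, outdir / "fdr_matrix.tsv")
            xio.write_expression_matrix(
                nes_matrix.nominal_p, outdir / "nominal_p_matrix.tsv"
            )
            manifest["records"]["compare_cells"] = int(nes_matrix.nes.size)
            did_anything = True
        if not did_anything:
            manifest["records"]["gsea_sets"] = None

    run_stage("quantify", stage_quantify)
    run_stage("collapse", stage_collapse)
    run_stage("enrich", stage_enrich)
    run_stage("project", stage_project)
    run_stage("ontology", stage_ontology)
    run_stage("gsea", stage_gsea)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
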