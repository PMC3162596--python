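"""Synthetic multi-tissue expression data with known planted structure.

The generator emulates the study design the pipeline targets: a handful of
tissues, one pooled library per tissue, a log-normal baseline abundance per
gene, disjoint modules of tissue-enriched genes planted at a configurable
fold change, multiplicative biological noise, Poisson read-count sampling
at a configurable depth, a partially many-to-many homology map into a
second species' id space, and annotation terms that overlap the planted
modules.  Every randomised step is driven by one seed, so a configuration
maps to a byte-identical fixture bundle.

Default abundance parameters are anchored to published bulk-tissue RNA-seq
summaries: roughly 62% of detected transcripts above 10 RPKM and a dynamic
range of ~5 decades, which a log-normal with ln-mean 2.84 (median ≈ 17
RPKM) and ln-sd 1.8 reproduces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .homology import HomologyMap
from .ontology import AnnotationSet

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_tissue_profiles",
           "sample_read_counts", "generate_homology_map", "generate_annotations",
           "generate_species_pair", "write_fixture_bundle"]

DEFAULT_TISSUES = ("swimbladder", "brain", "heart", "kidney")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    ``baseline_log_mean``/``baseline_log_sd`` are natural-log parameters of
    the per-gene log-normal baseline (units: RPKM); ``noise_cv`` is the
    coefficient of variation of the multiplicative per-cell noise;
    ``log2_fold`` is the planted enrichment (log2 units).  With one pooled
    library per tissue no biological-replicate variance exists, so
    ``noise_cv`` is a free parameter of the simulation, not an estimate.
    """

    seed: int = 0
    n_genes: int = 5000
    tissue_labels: tuple[str, ...] = DEFAULT_TISSUES
    n_enriched_per_tissue: int = 200
    log2_fold: float = 3.0
    baseline_log_mean: float = 2.84
    baseline_log_sd: float = 1.8
    noise_cv: float = 0.25
    total_reads_per_tissue: int = 10_000_000
    length_range_bp: tuple[int, int] = (500, 4000)
    homolog_coverage: float = 0.7
    multi_homolog_fraction: float = 0.2
    n_terms: int = 40
    unannotated_fraction: float = 0.4
    planted_term_overlap: int = 20

    def validate(self) -> None:
        if len(self.tissue_labels) < 2:
            raise ConfigError("tissue_labels: need at least 2 tissues")
        if len(set(self.tissue_labels)) != len(self.tissue_labels):
            raise ConfigError("tissue_labels: labels must be unique")
        if self.n_genes < 1:
            raise ConfigError("n_genes: must be >= 1")
        if self.n_enriched_per_tissue < 0:
            raise ConfigError("n_enriched_per_tissue: must be >= 0")
        if self.n_enriched_per_tissue * len(self.tissue_labels) > self.n_genes:
            raise ConfigError(
                "n_enriched_per_tissue: planted modules exceed n_genes"
            )
        if self.log2_fold < 0:
            raise ConfigError("log2_fold: must be >= 0")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv: must be >= 0")
        if self.total_reads_per_tissue < 0:
            raise ConfigError("total_reads_per_tissue: must be >= 0")
        lo, hi = self.length_range_bp
        if lo < 1 or hi < lo:
            raise ConfigError("length_range_bp: need 1 <= min <= max")
        for name in ("homolog_coverage", "multi_homolog_fraction",
                     "unannotated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1]")
        if self.n_terms < 0:
            raise ConfigError("n_terms: must be >= 0")
        if self.planted_term_overlap < 0:
            raise ConfigError("planted_term_overlap: must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure: the answer key for parameter-recovery scoring."""

    enriched_sets: Mapping[str, frozenset]
    term_plants: Mapping[str, str]
    homolog_map_truth: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "enriched_sets": {t: sorted(s) for t, s in self.enriched_sets.items()},
            "term_plants": dict(self.term_plants),
            "homolog_map_truth": {s: list(t) for s, t in self.homolog_map_truth.items()},
        }


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_tissue_profiles(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """True per-gene RPKM matrix plus the planted truth.

    Baselines are log-normal; each tissue's planted genes are multiplied by
    ``2**log2_fold`` in that tissue only; mean-one multiplicative log-normal
    noise with coefficient of variation ``noise_cv`` is applied per cell.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    tissues = list(config.tissue_labels)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                             config.n_genes)
    expr = np.tile(baseline[:, None], (1, len(tissues)))

    # Disjoint planted modules, drawn without replacement over all genes.
    n_plant = config.n_enriched_per_tissue * len(tissues)
    planted = rng.choice(config.n_genes, size=n_plant, replace=False)
    enriched_sets = {}
    for j, tissue in enumerate(tissues):
        block = planted[j * config.n_enriched_per_tissue:(j + 1) * config.n_enriched_per_tissue]
        expr[block, j] *= 2.0 ** config.log2_fold
        enriched_sets[tissue] = frozenset(genes[i] for i in block)

    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
        expr *= rng.lognormal(-sigma ** 2 / 2.0, sigma, expr.shape)

    matrix = pd.DataFrame(expr, index=pd.Index(genes, name="cluster"), columns=tissues)
    truth = SyntheticTruth(enriched_sets=enriched_sets, term_plants={})
    return matrix, truth


def sample_read_counts(
    truth_matrix: pd.DataFrame, config: SyntheticConfig
) -> dict[str, pd.DataFrame]:
    """Per-tissue count tables sampled from the true abundances.

    Transcript lengths are uniform over ``length_range_bp`` (one length per
    gene, shared across tissues); the expected count inverts the RPKM
    formula, ``rpkm * length_bp * total_reads / 1e9``, and realised counts
    are Poisson with that mean.
    """
    config.validate()
    if (truth_matrix.to_numpy() < 0).any():
        raise InputError("true abundance matrix contains negative values")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    lo, hi = config.length_range_bp
    lengths = rng.integers(lo, hi + 1, size=len(truth_matrix))
    out = {}
    for tissue in truth_matrix.columns:
        lam = (
            truth_matrix[tissue].to_numpy(float)
            * lengths
            * config.total_reads_per_tissue
            / 1e9
        )
        counts = rng.poisson(lam)
        out[tissue] = pd.DataFrame(
            {
                "transcript_id": truth_matrix.index,
                "cluster_id": truth_matrix.index,
                "length_bp": lengths,
                "read_count": counts,
            }
        ).reset_index(drop=True)
    return out


def generate_homology_map(config: SyntheticConfig) -> HomologyMap:
    """Partially many-to-many source→target map into a second species.

    A fraction ``homolog_coverage`` of genes receive at least one target; of
    those, a fraction ``multi_homolog_fraction`` receive a second (and
    third) target.  Target ids are unique, so with full coverage and no
    multi-mapping the map is a bijection.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    genes = _gene_ids(config.n_genes)
    n_mapped = int(round(config.homolog_coverage * config.n_genes))
    mapped_idx = np.sort(rng.choice(config.n_genes, size=n_mapped, replace=False))
    n_multi = int(round(config.multi_homolog_fraction * n_mapped))
    multi_idx = set(rng.choice(n_mapped, size=n_multi, replace=False).tolist())
    mapping: dict[str, tuple[str, ...]] = {}
    serial = 0
    for pos, gi in enumerate(mapped_idx):
        n_targets = 1 + (1 + int(rng.integers(0, 2)) if pos in multi_idx else 0)
        targets = tuple(f"Hs.{serial + k:06d}" for k in range(n_targets))
        serial += n_targets
        mapping[genes[gi]] = targets
    return HomologyMap(mapping=mapping, species="human")


def generate_annotations(
    config: SyntheticConfig, truth: SyntheticTruth
) -> tuple[list[AnnotationSet], SyntheticTruth]:
    """Annotation terms, some planted to overlap the enriched modules.

    One term per tissue contains exactly ``planted_term_overlap`` members of
    that tissue's enriched set (plus background filler); an exact fraction
    ``unannotated_fraction`` of genes belong to no term.  Returns the terms
    and a truth updated with the term→tissue plants.
    """
    config.validate()
    tissues = [t for t in truth.enriched_sets if truth.enriched_sets[t]]
    if config.planted_term_overlap > 0:
        for t in tissues:
            if config.planted_term_overlap > len(truth.enriched_sets[t]):
                raise ConfigError(
                    "planted_term_overlap: exceeds enriched-set size for tissue "
                    f"{t!r}"
                )
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    genes = _gene_ids(config.n_genes)

    overlap_members: dict[str, list[str]] = {}
    reserved: set = set()
    if config.planted_term_overlap > 0 and config.n_terms > 0:
        for t in tissues[: config.n_terms]:
            members = rng.choice(
                sorted(truth.enriched_sets[t]), size=config.planted_term_overlap,
                replace=False,
            ).tolist()
            overlap_members[t] = members
            reserved |= set(members)

    # Exact unannotated count, drawn from genes not reserved by plants.
    n_unann = int(round(config.unannotated_fraction * config.n_genes))
    candidates = sorted(set(genes) - reserved)
    if n_unann > len(candidates):
        raise ConfigError(
            "unannotated_fraction: not enough unreserved genes to leave unannotated"
        )
    unannotated = set(rng.choice(candidates, size=n_unann, replace=False).tolist())
    annotatable = sorted(set(genes) - unannotated - reserved)

    term_names = [f"TERM{i:04d}" for i in range(config.n_terms)]
    namespaces = ("Biological Process", "Molecular Function", "Cellular Component")
    members_of: dict[str, set] = {name: set() for name in term_names}
    term_plants: dict[str, str] = {}
    tissue_of_planted_term: dict[str, str] = {}
    for i, t in enumerate(overlap_members):
        name = term_names[i]
        members_of[name] |= set(overlap_members[t])
        term_plants[name] = t
        tissue_of_planted_term[name] = t

    # Every annotatable gene joins >= 1 term; a planted term never receives
    # extra genes from its own tissue's enriched set, keeping the configured
    # overlap exact.
    for g in annotatable:
        allowed = [
            name
            for name in term_names
            if name not in tissue_of_planted_term
            or g not in truth.enriched_sets[tissue_of_planted_term[name]]
        ]
        if not allowed:
            continue
        n_memberships = min(1 + int(rng.integers(0, 3)), len(allowed))
        for name in rng.choice(allowed, size=n_memberships, replace=False):
            members_of[name].add(g)

    terms = [
        AnnotationSet(
            term=name, namespace=namespaces[i % 3], genes=frozenset(members_of[name])
        )
        for i, name in enumerate(term_names)
    ]
    new_truth = SyntheticTruth(
        enriched_sets=truth.enriched_sets,
        term_plants=term_plants,
        homolog_map_truth=truth.homolog_map_truth,
    )
    return terms, new_truth


def generate_species_pair(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, HomologyMap, SyntheticTruth]:
    """Two species sharing tissue biology: matched planted modules, independent noise.

    The noise-free planted profile is generated once; two independent
    multiplicative-noise realisations stand in for the two species, and the
    second ("target") matrix is re-indexed to target-species homolog ids
    through the generated map (per-tissue maximum on many-to-one
    collisions).  Returns ``(source_matrix, target_matrix, homology_map,
    truth)`` where the truth's enriched sets are in source-species ids.
    """
    from .homology import project_matrix

    config.validate()
    clean_cfg = dataclasses.replace(config, noise_cv=0.0)
    m0, truth = generate_tissue_profiles(clean_cfg)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 4)))
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
        noise_a = rng.lognormal(-sigma ** 2 / 2.0, sigma, m0.shape)
        noise_b = rng.lognormal(-sigma ** 2 / 2.0, sigma, m0.shape)
    else:
        noise_a = noise_b = np.ones(m0.shape)
    source = m0 * noise_a
    hmap = generate_homology_map(config)
    target = project_matrix(m0 * noise_b, hmap)
    truth = SyntheticTruth(
        enriched_sets=truth.enriched_sets,
        term_plants=truth.term_plants,
        homolog_map_truth=hmap.mapping,
    )
    return source, target, hmap, truth


def write_fixture_bundle(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate everything and write the TSV/JSON fixture bundle.

    Files: ``expression.tsv`` (genes × tissues), ``counts_<tissue>.tsv``,
    ``homologs.tsv`` (source, target, rank), ``annotations.tsv`` (term,
    namespace, gene), ``truth.json``.  Identical configs yield byte-identical
    bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_tissue_profiles(config)
    counts = sample_read_counts(matrix, config)
    hmap = generate_homology_map(config)
    truth = SyntheticTruth(
        enriched_sets=truth.enriched_sets,
        term_plants=truth.term_plants,
        homolog_map_truth=hmap.mapping,
    )
    terms, truth = generate_annotations(config, truth)

    paths: dict[str, Path] = {}
    paths["expression"] = outdir / "expression.tsv"
    matrix.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    for tissue, tbl in counts.items():
        p = outdir / f"counts_{tissue}.tsv"
        tbl.to_csv(p, sep="\t", index=False)
        paths[f"counts_{tissue}"] = p
    rows = [
        {"source": s, "target": t, "rank": r + 1}
        for s, targets in hmap.mapping.items()
        for r, t in enumerate(targets)
    ]
    paths["homologs"] = outdir / "homologs.tsv"
    pd.DataFrame(rows, columns=["source", "target", "rank"]).to_csv(
        paths["homologs"], sep="\t", index=False
    )
    ann_rows = [
        {"term": a.term, "namespace": a.namespace, "gene": g}
        for a in terms
        for g in sorted(a.genes)
    ]
    paths["annotations"] = outdir / "annotations.tsv"
    pd.DataFrame(ann_rows, columns=["term", "namespace", "gene"]).to_csv(
        paths["annotations"], sep="\t", index=False
    )
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    return paths
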