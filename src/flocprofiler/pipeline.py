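"""End-to-end orchestration: run every analysis stage on a set of input
tables and aggregate one machine-readable summary.

The summary JSON is a pure aggregation of the per-stage outputs — every
count in it can be re-derived from the stage tables — and carries a
provenance block (config hash, package version) so identical configurations
yield identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .cazymes import cazy_summary, class_totals
from .community import CommunityProfile, build_profile, mapping_rate
from .errors import FlocProfilerError
from .io import (
    GeneTable,
    GenomeRecord,
    SimilarityRecord,
    Taxonomy,
    read_abundance_matrix,
    read_gene_table,
    read_genome_records,
    read_pathway_definitions,
    read_similarity_table,
    read_taxonomy_table,
)
from .pathways import (
    PathwayCall,
    apply_dsrab_orientation,
    builtin_pathway_definitions,
    call_pathways,
    calls_frame,
    marker_call,
    pathway_abundance_matrix,
    sox_rdsr_cooccurrence,
)
from .quality import (
    QualityAssessment,
    TierThresholds,
    assess,
    assessment_frame,
    count_unclassified,
    tier_counts,
)
from .screening import classify_dsrab, novelty_calls, novelty_counts, screen_hnad

logger = logging.getLogger("flocprofiler")


class RunConfig(BaseModel):
    """All thresholds and input paths of one pipeline run; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    genome_records: str | None = None
    gene_table: str | None = None
    counts: str | None = None
    totals: str | None = None
    taxonomy: str | None = None
    bulk_genes: str | None = None
    dsrab_similarity: str | None = None
    hnad_similarity: str | None = None
    novelty_similarity: str | None = None
    pathway_definitions: str | None = None
    vocabulary: str | None = None
    output_dir: str = "flocprofiler_out"
    seed: int = 0

    high_completeness: float = 90.0
    high_contamination: float = 5.0
    medium_completeness: float = 50.0
    medium_contamination: float = 10.0
    medium_contamination_inclusive: bool = False
    mimag_min_trna: int = 18
    detection_threshold: float = 0.0
    core_threshold: float = 0.01
    mean_over_detected_only: bool = False
    genus_identity: float = 94.5
    species_identity: float = 98.7
    hnad_identity: float = 60.0
    hnad_coverage: float = 70.0
    dsrab_margin: float = 2.0
    cazy_rank: str = "family"

    def tier_thresholds(self) -> TierThresholds:
        return TierThresholds(
            high_completeness=self.high_completeness,
            high_contamination=self.high_contamination,
            medium_completeness=self.medium_completeness,
            medium_contamination=self.medium_contamination,
            medium_contamination_inclusive=self.medium_contamination_inclusive,
            mimag_min_trna=self.mimag_min_trna,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory outputs of :func:`run_all`."""

    assessments: list[QualityAssessment] = field(default_factory=list)
    profile: CommunityProfile | None = None
    pathway_calls: list[PathwayCall] = field(default_factory=list)
    dsrab_orientation: dict[str, str] = field(default_factory=dict)
    hnad_results: dict = field(default_factory=dict)
    novelty: dict = field(default_factory=dict)
    cazy_by_class: pd.DataFrame | None = None
    cazy_by_family: pd.DataFrame | None = None
    pathway_zscores: pd.DataFrame | None = None
    zscore_flags: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


_NON_ANALYTIC_FIELDS = {
    "genome_records", "gene_table", "counts", "totals", "taxonomy",
    "bulk_genes", "dsrab_similarity", "hnad_similarity", "novelty_similarity",
    "pathway_definitions", "vocabulary", "output_dir",
}


def _config_hash(config: RunConfig) -> str:
    # hash only the analytic knobs: where inputs live and outputs go does
    # not change what is computed
    payload = json.dumps(
        config.model_dump(exclude=_NON_ANALYTIC_FIELDS), sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(
    config: RunConfig,
    *,
    genome_records: Sequence[GenomeRecord] | None = None,
    gene_table: GeneTable | None = None,
    abundance=None,
    taxonomies: Mapping[str, Taxonomy] | None = None,
    bulk_genes: pd.DataFrame | None = None,
    dsrab_similarity: Sequence[SimilarityRecord] | None = None,
    hnad_similarity: Sequence[SimilarityRecord] | None = None,
    novelty_similarity: Sequence[SimilarityRecord] | None = None,
    hnad_marker_lengths: Mapping[str, int] | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run every configured stage and aggregate the summary.

    Inputs may be passed in memory (keyword arguments) or read from the
    paths in ``config``; in-memory objects win.  Any stage failure aborts
    with the stage name and cause.
    """
    t0 = time.time()
    result = PipelineResult()
    summary: dict = {
        "provenance": {
            "package_version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
        }
    }

    def stage(name):
        logger.info("stage %s at %.2fs", name, time.time() - t0)

    try:
        stage("load")
        if genome_records is None and config.genome_records:
            genome_records = read_genome_records(config.genome_records)
        if gene_table is None and config.gene_table:
            gene_table = read_gene_table(config.gene_table, config.vocabulary)
        if abundance is None and config.counts and config.totals:
            abundance = read_abundance_matrix(config.counts, config.totals)
        if taxonomies is None and config.taxonomy:
            taxonomies = read_taxonomy_table(config.taxonomy)
        if bulk_genes is None and config.bulk_genes:
            bulk_genes = pd.read_csv(config.bulk_genes, sep="\t")
        if dsrab_similarity is None and config.dsrab_similarity:
            dsrab_similarity = read_similarity_table(config.dsrab_similarity)
        if hnad_similarity is None and config.hnad_similarity:
            hnad_similarity = read_similarity_table(config.hnad_similarity)
        if novelty_similarity is None and config.novelty_similarity:
            novelty_similarity = read_similarity_table(config.novelty_similarity)
        if config.pathway_definitions:
            definitions = read_pathway_definitions(config.pathway_definitions)
        else:
            definitions = builtin_pathway_definitions()
    except FlocProfilerError as exc:
        raise FlocProfilerError(f"stage 'load' failed: {exc}") from exc

    # --- quality -------------------------------------------------------------
    if genome_records is not None:
        stage("quality")
        thresholds = config.tier_thresholds()
        result.assessments = assess(genome_records, thresholds)
        summary["quality"] = tier_counts(result.assessments)

    # --- taxonomy ------------------------------------------------------------
    if taxonomies is not None:
        stage("taxonomy")
        from .io import RANKS

        summary["unclassified_by_rank"] = {
            rank: count_unclassified(taxonomies, rank) for rank in RANKS
        }

    # --- community -----------------------------------------------------------
    if abundance is not None:
        stage("community")
        result.profile = build_profile(
            abundance,
            detection_threshold=config.detection_threshold,
            core_threshold=config.core_threshold,
            mean_over_detected_only=config.mean_over_detected_only,
        )
        cats = result.profile.category_counts()
        _, group_means = mapping_rate(abundance)
        summary["community"] = {
            "n_mags": len(result.profile.mag_ids),
            "n_samples": abundance.n_samples,
            "MfA": cats["MfA"],
            "LfA": cats["LfA"],
            "core": len(result.profile.core_set()),
            "mean_mapping_rate_percent": group_means["all"],
        }

    # --- dsrAB orientation (needed before pathway gating) ---------------------
    if dsrab_similarity is not None:
        stage("dsrab")
        result.dsrab_orientation = classify_dsrab(
            dsrab_similarity, margin=config.dsrab_margin
        )
        summary["dsrab_orientation"] = {
            label: sum(1 for v in result.dsrab_orientation.values() if v == label)
            for label in ("oxidative", "reductive", "ambiguous")
        }

    # --- pathways & markers ---------------------------------------------------
    if gene_table is not None:
        stage("pathways")
        calls = call_pathways(gene_table, definitions)
        calls = apply_dsrab_orientation(calls, result.dsrab_orientation)
        result.pathway_calls = calls
        complete_counts: dict[str, int] = {}
        for c in calls:
            if c.complete:
                complete_counts[c.pathway_id] = complete_counts.get(c.pathway_id, 0) + 1
        markers = {"denitrification": 0, "dnra": 0, "sox_oxidation": 0}
        known = gene_table.frame[~gene_table.frame["unknown_symbol"]]
        for _, group in known.groupby("scope_id"):
            genes = frozenset(group["symbol"].dropna())
            for process in markers:
                if marker_call(genes, process):
                    markers[process] += 1
        sox_rdsr = sox_rdsr_cooccurrence(calls, result.dsrab_orientation)
        summary["pathways"] = {
            "complete_by_pathway": {
                d.pathway_id: complete_counts.get(d.pathway_id, 0) for d in definitions
            },
            "marker_counts": markers,
            "sox_rdsr_cooccurrence": len(sox_rdsr),
        }

        if taxonomies is not None:
            stage("cazy")
            result.cazy_by_class, result.cazy_by_family = cazy_summary(
                gene_table, taxonomies, config.cazy_rank
            )
            summary["cazy"] = {
                "total_genes": int(len(gene_table.cazy_rows())),
                "class_totals": class_totals(result.cazy_by_class),
            }

    # --- bulk pathway x sample z-scores ---------------------------------------
    if bulk_genes is not None and len(bulk_genes):
        stage("zscore")
        result.pathway_zscores, result.zscore_flags = pathway_abundance_matrix(
            bulk_genes, definitions
        )

    # --- HN-AD screen ----------------------------------------------------------
    if hnad_similarity is not None:
        stage("hnad")
        from .simulate import HNAD_MARKER_LENGTHS

        lengths = dict(hnad_marker_lengths or HNAD_MARKER_LENGTHS)
        result.hnad_results = screen_hnad(
            hnad_similarity,
            lengths,
            identity_threshold=config.hnad_identity,
            coverage_threshold=config.hnad_coverage,
        )
        summary["hnad"] = {
            "screened": len(result.hnad_results),
            "positive": sum(1 for r in result.hnad_results.values() if r.positive),
        }

    # --- 16S novelty -----------------------------------------------------------
    if novelty_similarity is not None:
        stage("novelty")
        result.novelty = novelty_calls(novelty_similarity)
        summary["novelty"] = novelty_counts(result.novelty)

    result.summary = summary
    if write:
        stage("write")
        _write_outputs(result, config)
    stage("done")
    return result


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.assessments:
        assessment_frame(result.assessments).to_csv(
            outdir / "quality_assessments.tsv", sep="\t", index=False
        )
    if result.profile is not None:
        frame = result.profile.frame.reset_index()
        frame.to_csv(outdir / "community_profile.tsv", sep="\t", index=False)
        pd.Series(sorted(result.profile.core_set()), name="mag_id").to_csv(
            outdir / "core_members.tsv", sep="\t", index=False
        )
    if result.pathway_calls:
        calls_frame(result.pathway_calls).to_csv(
            outdir / "pathway_calls.tsv", sep="\t", index=False
        )
    if result.cazy_by_class is not None and not result.cazy_by_class.empty:
        result.cazy_by_class.to_csv(outdir / "cazy_by_class.tsv", sep="\t")
        result.cazy_by_family.to_csv(outdir / "cazy_by_family.tsv", sep="\t")
    if result.pathway_zscores is not None:
        result.pathway_zscores.to_csv(outdir / "pathway_zscores.tsv", sep="\t")
    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
    )


def run_from_config_file(path: str | Path) -> PipelineResult:
    return run_all(RunConfig.from_yaml(path))
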