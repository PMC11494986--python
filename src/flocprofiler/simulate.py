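"""Synthetic genome-resolved community generator with ground truth.

The generator emulates the derived tables a genome-centric metagenome
analysis consumes — genome quality records, long-format gene annotations,
a MAG-by-sample mapped-read count matrix, GTDB-style taxonomy strings and
pairwise similarity tables — not the sequencing reads themselves.  Its
mechanisms mirror the failure modes the analysis rules guard against:

* every endowed gene is emitted independently with probability C/100, so
  genome incompleteness causes gene dropout and missed pathway calls;
* foreign genes drawn from other taxa's endowments are injected at a rate
  proportional to contamination X, so contamination can create spurious
  pathway calls;
* per-sample presence is Bernoulli occupancy and read counts are a single
  multinomial draw over present genomes with log-normal weights, with an
  unmapped background bin absorbing the remaining reads.

Everything is reproducible from the integer seed alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .community import CORE_MEAN_RA_THRESHOLD, mfa_cutoff
from .errors import ConfigError
from .io import (
    AbundanceMatrix,
    GeneTable,
    GenomeRecord,
    SimilarityRecord,
    Taxonomy,
    load_vocabulary,
    write_abundance_matrix,
    write_gene_table,
    write_genome_records,
    write_similarity_table,
    write_taxonomy_table,
)
from .pathways import builtin_pathway_definitions
from .quality import classify_tier
from .screening import (
    GENUS_IDENTITY_THRESHOLD,
    HNAD_MARKERS,
    OXIDATIVE,
    REDUCTIVE,
    SPECIES_IDENTITY_THRESHOLD,
)

# ---------------------------------------------------------------------------
# Lineage pool: families recurrent in flocculated-aggregate communities,
# with their GTDB phylum/class/order placement and example genera.
# ---------------------------------------------------------------------------

_LINEAGES: list[tuple[str, str, str, str, list[str]]] = [
    ("Pseudomonadota", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae",
     ["Marivita", "Ruegeria", "Dinoroseobacter", "Albidovulum", "Donghicola"]),
    ("Pseudomonadota", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae",
     ["Alteraurantiacibacter"]),
    ("Pseudomonadota", "Alphaproteobacteria", "Micavibrionales", "Micavibrionaceae",
     ["Micavibrio"]),
    ("Pseudomonadota", "Gammaproteobacteria", "Pseudomonadales", "Halieaceae",
     ["Halioglobus", "Aequoribacter"]),
    ("Pseudomonadota", "Gammaproteobacteria", "Steroidobacterales", "Woeseiaceae",
     ["Woeseia"]),
    ("Pseudomonadota", "Gammaproteobacteria", "Arenicellales", "Arenicellaceae",
     ["Arenicella"]),
    ("Bacteroidota", "Bacteroidia", "Flavobacteriales", "Flavobacteriaceae",
     ["Muricauda", "Polaribacter", "Maribacter"]),
    ("Bacteroidota", "Bacteroidia", "Chitinophagales", "Saprospiraceae",
     ["Phaeodactylibacter"]),
    ("Bacteroidota", "Bacteroidia", "Cytophagales", "Cyclobacteriaceae",
     ["Fulvivirga"]),
    ("Planctomycetota", "Planctomycetia", "Planctomycetales", "Planctomycetaceae",
     ["Planctomyces"]),
    ("Actinomycetota", "Actinomycetia", "Micrococcales", "Microbacteriaceae",
     ["Microbacterium"]),
    ("Myxococcota", "Polyangia", "Nannocystales", "Nannocystaceae",
     ["Nannocystis"]),
]

#: CAZy family pool with sampling weights loosely following the observed
#: dominance of glycoside hydrolases over lyases/esterases.
_CAZY_POOL: list[tuple[str, float]] = [
    ("GH13", 0.16), ("GH43", 0.12), ("GH16", 0.09), ("GH5", 0.08),
    ("GH3", 0.05), ("GH2", 0.05), ("GT2", 0.10), ("GT4", 0.08),
    ("PL1", 0.05), ("PL9", 0.03), ("PL10", 0.02), ("PL12", 0.02),
    ("CE1", 0.04), ("CE10", 0.03), ("AA3", 0.03), ("CBM50", 0.05),
]

_HOUSEKEEPING = ("recA", "rpoB", "gyrB", "dnaK", "ftsZ",
                 "rpsC", "rplB", "secY", "infB", "pheS")

#: Reference protein lengths (aa) for the HN-AD marker screen.
HNAD_MARKER_LENGTHS = {"DnfA": 450, "DnfB": 350, "DnfC": 300, "POD": 300}

#: Default per-taxon pathway endowment probabilities, set to roughly the
#: per-genome prevalence observed in flocculated-aggregate communities
#: (denitrifiers ~1/4 of genomes, GS-GOGAT ~28%, sox ~10%, DNRA ~6%,
#: oxidative-dsrAB rare, anammox and autotrophic nitrification absent or
#: nearly so).
DEFAULT_PATHWAY_PROBABILITIES: dict[str, float] = {
    "denitrification": 0.25,
    "dnra": 0.06,
    "assimilatory_nitrate_reduction": 0.10,
    "autotrophic_nitrification": 0.01,
    "anammox": 0.0,
    "nitrogen_fixation": 0.05,
    "gs_gogat": 0.28,
    "gdh": 0.10,
    "sox": 0.10,
    "rdsr": 0.02,
    "sulfate_reduction": 0.02,
}


class SimulationConfig(BaseModel):
    """Knobs of the synthetic community; defaults are the study conditions
    (11 metagenomes subsampled to 10 million PE reads each)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_taxa: int = 40
    n_mags: int = 120
    n_samples: int = 11
    pathway_probabilities: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PATHWAY_PROBABILITIES)
    )
    #: Beta(a, b) shape of completeness, scaled onto completeness_range.
    completeness_beta: tuple[float, float] = (5.0, 2.0)
    completeness_range: tuple[float, float] = (50.0, 100.0)
    #: exponential scale of contamination, truncated onto contamination_range.
    contamination_scale: float = 2.0
    contamination_range: tuple[float, float] = (0.0, 10.0)
    #: expected injected foreign genes per percentage point of contamination.
    foreign_genes_per_contamination_pct: float = 0.5
    occupancy_probability: float = 0.7
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    total_reads: int = 10_000_000
    #: fraction of each sample's reads not mapping to any genome.
    background_fraction: float = 0.4
    mean_cazy_genes: float = 15.0
    #: drop one contiguous arc of the gene order instead of independent coin flips.
    block_dropout: bool = False
    emit_bulk: bool = True

    @model_validator(mode="after")
    def _check(self):
        for pid, p in self.pathway_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"endowment probability for {pid!r} outside [0,1]: {p}")
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.n_taxa < 1 or self.n_mags < 1:
            raise ConfigError("need at least one taxon and one MAG")
        if self.total_reads <= 0:
            raise ConfigError("total_reads must be positive")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ConfigError("background_fraction must be in [0, 1)")
        if not 0.0 <= self.occupancy_probability <= 1.0:
            raise ConfigError("occupancy_probability must be in [0, 1]")
        lo, hi = self.completeness_range
        if not (0 <= lo <= hi <= 100):
            raise ConfigError("completeness_range must satisfy 0 <= lo <= hi <= 100")
        if self.contamination_scale < 0:
            raise ConfigError("contamination_scale must be >= 0")
        known = {d.pathway_id for d in builtin_pathway_definitions()}
        unknown = set(self.pathway_probabilities) - known
        if unknown:
            raise ConfigError(f"unknown pathway ids in endowments: {sorted(unknown)}")
        return self


@dataclass
class GroundTruth:
    """Everything the generator decided, for downstream recovery checks."""

    mag_taxon: dict[str, str]
    endowed_pathways: dict[str, frozenset[str]]
    endowed_symbols: dict[str, frozenset[str]]
    completeness: dict[str, float]
    contamination: dict[str, float]
    tier: dict[str, str]
    presence: pd.DataFrame  # MAG x sample bool
    abundance_fraction: pd.DataFrame  # MAG x sample, fraction of total reads
    mapped_fraction: dict[str, float]  # per-sample designed mapped fraction
    core_set: set[str]
    mfa_set: set[str]
    dsrab_orientation: dict[str, str]
    novelty_call: dict[str, str]


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome_records: list[GenomeRecord]
    gene_table: GeneTable
    abundance: AbundanceMatrix
    taxonomies: dict[str, Taxonomy]
    bulk_genes: pd.DataFrame  # sample_id, gene_id, symbol
    dsrab_similarity: list[SimilarityRecord]
    hnad_similarity: list[SimilarityRecord]
    novelty_similarity: list[SimilarityRecord]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------


@dataclass
class _TaxonSpec:
    taxon_id: str
    taxonomy: Taxonomy
    pathways: frozenset[str]
    step_choice: dict[str, tuple[frozenset[str], ...]]  # chosen alternative per step
    symbols: frozenset[str]
    cazy_families: tuple[str, ...]
    dsr_orientation: str | None


def _draw_taxa(rng: np.random.Generator, config: SimulationConfig) -> list[_TaxonSpec]:
    defs = {d.pathway_id: d for d in builtin_pathway_definitions()}
    taxa = []
    for i in range(config.n_taxa):
        lineage = _LINEAGES[int(rng.integers(len(_LINEAGES)))]
        phylum, class_, order, family, genera = lineage
        genus = genera[int(rng.integers(len(genera)))] if rng.random() < 0.7 else ""
        species = f"{genus.lower()}_sp{i:03d}" if genus and rng.random() < 0.07 else ""
        taxonomy = Taxonomy("Bacteria", phylum, class_, order, family, genus, species)

        endowed = {
            pid for pid, p in config.pathway_probabilities.items() if rng.random() < p
        }
        # a genome's dsrAB runs in one direction only
        if "rdsr" in endowed and "sulfate_reduction" in endowed:
            endowed.discard("sulfate_reduction")
        orientation = None
        if "rdsr" in endowed:
            orientation = OXIDATIVE
        elif "sulfate_reduction" in endowed:
            orientation = REDUCTIVE

        step_choice: dict[str, tuple[frozenset[str], ...]] = {}
        symbols: set[str] = set(_HOUSEKEEPING)
        for pid in endowed:
            chosen = tuple(
                step[int(rng.integers(len(step)))] for step in defs[pid].steps
            )
            step_choice[pid] = chosen
            for alt in chosen:
                symbols |= alt

        n_cazy = int(rng.poisson(config.mean_cazy_genes))
        fams, weights = zip(*_CAZY_POOL)
        w = np.asarray(weights) / sum(weights)
        cazy = tuple(rng.choice(fams, size=n_cazy, p=w)) if n_cazy else ()

        taxa.append(
            _TaxonSpec(
                taxon_id=f"T{i:03d}",
                taxonomy=taxonomy,
                pathways=frozenset(endowed),
                step_choice=step_choice,
                symbols=frozenset(symbols),
                cazy_families=cazy,
                dsr_orientation=orientation,
            )
        )
    return taxa


def _draw_quality(
    rng: np.random.Generator, config: SimulationConfig, n: int
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = config.completeness_range
    if hi > lo:
        completeness = lo + (hi - lo) * rng.beta(*config.completeness_beta, size=n)
    else:
        completeness = np.full(n, float(lo))
    xlo, xhi = config.contamination_range
    if config.contamination_scale > 0:
        contamination = rng.exponential(config.contamination_scale, size=n)
        # truncate by resampling via modulo fold into [xlo, xhi)
        out_of_range = contamination >= xhi
        while out_of_range.any():
            contamination[out_of_range] = rng.exponential(
                config.contamination_scale, size=int(out_of_range.sum())
            )
            out_of_range = contamination >= xhi
        contamination = np.maximum(contamination, xlo)
    else:
        contamination = np.full(n, float(xlo))
    return np.round(completeness, 2), np.round(contamination, 2)


def sample_counts(
    rng: np.random.Generator,
    presence: pd.DataFrame,
    weights: pd.Series,
    total_reads: int,
    background_fraction: float,
) -> pd.DataFrame:
    """Multinomial mapped-read counts per sample over present genomes.

    For each sample the present genomes share ``1 - background_fraction`` of
    the probability mass in proportion to their weights; the background bin
    absorbs the rest and is dropped from the returned matrix.
    """
    counts = pd.DataFrame(
        0, index=presence.index, columns=presence.columns, dtype=np.int64
    )
    for sample in presence.columns:
        mask = presence[sample].to_numpy()
        if not mask.any():
            continue
        w = weights.to_numpy()[mask]
        probs = (1.0 - background_fraction) * w / w.sum()
        probs = np.append(probs, 1.0 - probs.sum())  # background bin
        draw = rng.multinomial(total_reads, probs)
        counts.loc[presence.index[mask], sample] = draw[:-1]
    return counts


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate one synthetic community data set plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    vocab = load_vocabulary()
    taxa = _draw_taxa(rng, config)

    mag_ids = [f"MAG{i:04d}" for i in range(config.n_mags)]
    taxon_of = {
        m: taxa[int(rng.integers(len(taxa)))] for m in mag_ids
    }
    completeness, contamination = _draw_quality(rng, config, config.n_mags)

    # --- genome records -----------------------------------------------------
    records = []
    for i, mag in enumerate(mag_ids):
        c = completeness[i]
        rrna = frozenset(
            g for g in ("5S", "16S", "23S") if rng.random() < 0.6 * c / 100.0
        )
        records.append(
            GenomeRecord(
                mag_id=mag,
                completeness=float(c),
                contamination=float(contamination[i]),
                genome_size=int(np.clip(rng.lognormal(15.0, 0.45), 2e5, 1.3e7)),
                n_contigs=int(1 + rng.geometric(1.0 / 280.0)),
                gc=float(np.clip(rng.normal(50.0, 8.0), 25.0, 75.0)),
                rrna_present=rrna,
                trna_count=int(rng.binomial(46, 0.9 * c / 100.0)),
                domain_label="bacteria",
            )
        )

    # --- gene tables ---------------------------------------------------------
    rows = []
    emitted_symbols: dict[str, set[str]] = {}
    foreign_pools: dict[str, list[str]] = {
        t.taxon_id: sorted(
            set().union(
                *(s.symbols for s in taxa if s.taxon_id != t.taxon_id), set()
            )
            - set(_HOUSEKEEPING)
        )
        for t in taxa
    }
    for i, mag in enumerate(mag_ids):
        spec = taxon_of[mag]
        keep_p = completeness[i] / 100.0
        gene_no = 0
        kept: set[str] = set()
        symbols = sorted(spec.symbols)
        if config.block_dropout:
            # drop one contiguous arc of the (circular) gene order instead of
            # independent coin flips; arc length matches the incompleteness
            n = len(symbols)
            n_drop = int(round((1.0 - keep_p) * n))
            start = int(rng.integers(n)) if n else 0
            dropped = {symbols[(start + j) % n] for j in range(n_drop)}
            emit = [s for s in symbols if s not in dropped]
        else:
            emit = [s for s in symbols if rng.random() < keep_p]
        for sym in emit:
            rows.append((mag, f"g{gene_no:05d}", sym, None, None))
            kept.add(sym)
            gene_no += 1
        for fam in spec.cazy_families:
            if rng.random() < keep_p:
                rows.append((mag, f"g{gene_no:05d}", "cazyme", None, fam))
                gene_no += 1
        # contamination injects genes from other taxa's repertoires
        n_foreign = int(
            rng.poisson(config.foreign_genes_per_contamination_pct * contamination[i])
        )
        foreign_pool = foreign_pools[spec.taxon_id]
        for _ in range(n_foreign):
            if not foreign_pool:
                break
            sym = foreign_pool[int(rng.integers(len(foreign_pool)))]
            rows.append((mag, f"g{gene_no:05d}", sym, None, None))
            kept.add(sym)
            gene_no += 1
        emitted_symbols[mag] = kept

    gene_frame = pd.DataFrame(
        rows, columns=["scope_id", "gene_id", "symbol", "ko_id", "cazy_family"]
    )
    gene_frame["unknown_symbol"] = ~gene_frame["symbol"].isin(vocab)
    gene_table = GeneTable(gene_frame)

    # --- abundance -----------------------------------------------------------
    samples = [f"S{j:02d}" for j in range(config.n_samples)]
    presence = pd.DataFrame(
        rng.random((config.n_mags, config.n_samples)) < config.occupancy_probability,
        index=mag_ids,
        columns=samples,
    )
    weights = pd.Series(
        rng.lognormal(config.lognormal_mu, config.lognormal_sigma, config.n_mags),
        index=mag_ids,
    )
    counts = sample_counts(
        rng, presence, weights, config.total_reads, config.background_fraction
    )
    totals = pd.Series(config.total_reads, index=samples, dtype=np.int64)
    abundance = AbundanceMatrix(counts, totals)

    # designed (expected) abundance fractions and the core they imply
    frac = pd.DataFrame(0.0, index=mag_ids, columns=samples)
    for sample in samples:
        mask = presence[sample]
        if mask.any():
            w = weights[mask]
            frac.loc[mask, sample] = (
                (1.0 - config.background_fraction) * w / w.sum()
            )
    true_ra = 100.0 * frac
    freq = presence.sum(axis=1).astype(int)
    cutoff = mfa_cutoff(config.n_samples)
    mfa_set = set(freq.index[freq >= cutoff])
    core_set = {
        m
        for m in mag_ids
        if m in mfa_set and float(true_ra.loc[m].mean()) > CORE_MEAN_RA_THRESHOLD
    }

    # --- bulk (metagenome-contig) annotations per sample ---------------------
    bulk_rows = []
    if config.emit_bulk:
        genes_by_mag = {
            str(mag): list(zip(sub["gene_id"], sub["symbol"]))
            for mag, sub in gene_frame.groupby("scope_id")
        }
        for sample in samples:
            for mag in mag_ids:
                if not presence.loc[mag, sample]:
                    continue
                for gid, sym in genes_by_mag.get(mag, ()):
                    bulk_rows.append((sample, f"{mag}:{gid}", sym))
    bulk_genes = pd.DataFrame(bulk_rows, columns=["sample_id", "gene_id", "symbol"])

    # --- similarity tables ----------------------------------------------------
    dsr_records: list[SimilarityRecord] = []
    dsr_truth: dict[str, str] = {}
    for mag in mag_ids:
        spec = taxon_of[mag]
        if spec.dsr_orientation is None:
            continue
        if not {"dsrA", "dsrB"} <= emitted_symbols[mag]:
            continue
        right = float(rng.uniform(75.0, 95.0))
        wrong = right - float(rng.uniform(5.0, 25.0))
        other = OXIDATIVE if spec.dsr_orientation == REDUCTIVE else REDUCTIVE
        dsr_records.append(
            SimilarityRecord(mag, f"ref_{spec.dsr_orientation}", spec.dsr_orientation,
                             round(right, 1), 380)
        )
        dsr_records.append(
            SimilarityRecord(mag, f"ref_{other}", other, round(max(wrong, 30.0), 1), 380)
        )
        dsr_truth[mag] = spec.dsr_orientation

    hnad_records: list[SimilarityRecord] = []
    for mag in mag_ids:
        if rng.random() < 0.2:  # only some genomes align to the markers at all
            for marker in HNAD_MARKERS:
                ident = float(rng.uniform(20.0, 40.0))
                length = int(
                    HNAD_MARKER_LENGTHS[marker] * rng.uniform(0.8, 1.0)
                )
                hnad_records.append(
                    SimilarityRecord(mag, f"ref_{marker}", marker,
                                     round(ident, 1), length)
                )

    novelty_records: list[SimilarityRecord] = []
    novelty_truth: dict[str, str] = {}
    for rec in records:
        if "16S" not in rec.rrna_present:
            continue
        u = rng.random()
        if u < 0.50:
            ident = float(rng.uniform(80.0, GENUS_IDENTITY_THRESHOLD - 0.01))
            call = "novel_genus"
        elif u < 0.87:
            ident = float(
                rng.uniform(GENUS_IDENTITY_THRESHOLD, SPECIES_IDENTITY_THRESHOLD - 0.01)
            )
            call = "novel_species"
        else:
            ident = float(rng.uniform(SPECIES_IDENTITY_THRESHOLD, 100.0))
            call = "known_species"
        novelty_records.append(
            SimilarityRecord(rec.mag_id, "ref_16S", "16S", round(ident, 2), 1400)
        )
        novelty_truth[rec.mag_id] = call

    truth = GroundTruth(
        mag_taxon={m: taxon_of[m].taxon_id for m in mag_ids},
        endowed_pathways={m: taxon_of[m].pathways for m in mag_ids},
        endowed_symbols={m: taxon_of[m].symbols for m in mag_ids},
        completeness={m: float(completeness[i]) for i, m in enumerate(mag_ids)},
        contamination={m: float(contamination[i]) for i, m in enumerate(mag_ids)},
        tier={
            m: classify_tier(float(completeness[i]), float(contamination[i]))
            for i, m in enumerate(mag_ids)
        },
        presence=presence,
        abundance_fraction=frac,
        mapped_fraction={
            s: float(frac[s].sum()) for s in samples
        },
        core_set=core_set,
        mfa_set=mfa_set,
        dsrab_orientation=dsr_truth,
        novelty_call=novelty_truth,
    )
    taxonomies = {m: taxon_of[m].taxonomy for m in mag_ids}
    return SimulationResult(
        config=config,
        genome_records=records,
        gene_table=gene_table,
        abundance=abundance,
        taxonomies=taxonomies,
        bulk_genes=bulk_genes,
        dsrab_similarity=dsr_records,
        hnad_similarity=hnad_records,
        novelty_similarity=novelty_records,
        ground_truth=truth,
    )


def write_outputs(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write every emitted table in the package's TSV dialects; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_records": outdir / "genome_records.tsv",
        "gene_table": outdir / "gene_table.tsv",
        "counts": outdir / "abundance_counts.tsv",
        "totals": outdir / "sample_totals.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "bulk_genes": outdir / "bulk_genes.tsv",
        "dsrab_similarity": outdir / "dsrab_similarity.tsv",
        "hnad_similarity": outdir / "hnad_similarity.tsv",
        "novelty_similarity": outdir / "novelty_similarity.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_genome_records(result.genome_records, paths["genome_records"])
    write_gene_table(result.gene_table, paths["gene_table"])
    write_abundance_matrix(result.abundance, paths["counts"], paths["totals"])
    write_taxonomy_table(result.taxonomies, paths["taxonomy"])
    result.bulk_genes.to_csv(paths["bulk_genes"], sep="\t", index=False)
    write_similarity_table(result.dsrab_similarity, paths["dsrab_similarity"])
    write_similarity_table(result.hnad_similarity, paths["hnad_similarity"])
    write_similarity_table(result.novelty_similarity, paths["novelty_similarity"])
    truth = result.ground_truth
    payload = {
        "mag_taxon": truth.mag_taxon,
        "endowed_pathways": {m: sorted(v) for m, v in truth.endowed_pathways.items()},
        "completeness": truth.completeness,
        "contamination": truth.contamination,
        "tier": truth.tier,
        "core_set": sorted(truth.core_set),
        "mfa_set": sorted(truth.mfa_set),
        "mapped_fraction": truth.mapped_fraction,
        "dsrab_orientation": truth.dsrab_orientation,
        "novelty_call": truth.novelty_call,
        "config": json.loads(result.config.model_dump_json()),
    }
    paths["ground_truth"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return paths


# ---------------------------------------------------------------------------
# recovery report
# ---------------------------------------------------------------------------


def recovery_report(truth: GroundTruth, pipeline_result) -> pd.DataFrame:
    """Per-stage precision/recall of pipeline outputs against the ground truth.

    ``pipeline_result`` is a :class:`flocprofiler.pipeline.PipelineResult`
    from the same simulation; mismatched MAG id sets raise an error.  An
    endowed pathway whose genes dropped out entirely counts as a false
    negative, not an error.
    """
    truth_mags = set(truth.mag_taxon)
    pipe_mags = {a.mag_id for a in pipeline_result.assessments}
    if truth_mags != pipe_mags:
        raise ConfigError(
            f"MAG id mismatch between truth and pipeline: "
            f"{sorted(truth_mags ^ pipe_mags)[:10]}"
        )

    rows = []

    # tier agreement
    agree = sum(
        1 for a in pipeline_result.assessments if truth.tier[a.mag_id] == a.tier
    )
    rows.append(
        {
            "stage": "tier",
            "tp": agree,
            "fp": len(pipe_mags) - agree,
            "fn": len(pipe_mags) - agree,
            "precision": agree / len(pipe_mags),
            "recall": agree / len(pipe_mags),
        }
    )

    # core recovery
    predicted_core = pipeline_result.profile.core_set()
    tp = len(predicted_core & truth.core_set)
    fp = len(predicted_core - truth.core_set)
    fn = len(truth.core_set - predicted_core)
    rows.append(
        {
            "stage": "core",
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": tp / max(tp + fp, 1),
            "recall": tp / max(tp + fn, 1),
        }
    )

    # pathway complete-call confusion over (MAG, pathway) pairs
    complete = {
        (c.scope_id, c.pathway_id)
        for c in pipeline_result.pathway_calls
        if c.complete
    }
    endowed = {
        (m, pid) for m, pids in truth.endowed_pathways.items() for pid in pids
    }
    tp = len(complete & endowed)
    fp = len(complete - endowed)
    fn = len(endowed - complete)
    rows.append(
        {
            "stage": "pathways",
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": tp / max(tp + fp, 1),
            "recall": tp / max(tp + fn, 1),
        }
    )
    return pd.DataFrame(rows).set_index("stage")
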