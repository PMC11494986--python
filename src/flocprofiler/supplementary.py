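"""Reproduce published headline counts from a study's supplementary tables.

These helpers re-apply the package's classification rules to per-genome
tables exported from a published study (quality estimates, taxonomy strings,
relative abundances, 16S identities, gene content, CAZyme counts), so that
each printed count can be re-derived by rule application alone.  The tables
must first be converted to the package's TSV dialects — see
docs/supplementary.md for the retrieval and conversion recipe; none are
bundled with the package.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .community import mfa_cutoff
from .errors import SchemaError
from .io import parse_taxonomy
from .pathways import builtin_pathway_definitions, marker_call, pathway_completeness
from .quality import TIER_HIGH, TIER_MEDIUM, classify_tier, count_unclassified
from .screening import classify_16s_novelty

#: expected files under the supplementary directory, package TSV dialect
EXPECTED_FILES = {
    "quality": "quality.tsv",  # mag_id, completeness, contamination
    "taxonomy": "taxonomy.tsv",  # mag_id, taxonomy (GTDB string)
    "relative_abundance": "relative_abundance.tsv",  # mag_id + one column per metagenome, percent
    "gene_content": "gene_content.tsv",  # mag_id, symbol (one row per gene)
    "cazy_counts": "cazy_counts.tsv",  # any table of CAZy gene counts; all numeric cells summed
    "novelty_identity": "novelty_identity.tsv",  # mag_id, best_identity
}


def tier_count_reproduction(quality: pd.DataFrame) -> dict[str, int]:
    """Apply the tier rule to per-genome completeness/contamination columns."""
    for col in ("completeness", "contamination"):
        if col not in quality.columns:
            raise SchemaError(f"quality table missing column {col!r}")
    tiers = [
        classify_tier(float(c), float(x))
        for c, x in zip(quality["completeness"], quality["contamination"])
    ]
    return {
        "high": sum(t == TIER_HIGH for t in tiers),
        "medium": sum(t == TIER_MEDIUM for t in tiers),
    }


def species_unclassified_reproduction(taxonomy: pd.DataFrame) -> int:
    """Count genomes whose GTDB string is unclassified at the species rank."""
    parsed = [parse_taxonomy(s) for s in taxonomy["taxonomy"]]
    return count_unclassified(parsed, "species")


def mfa_count_reproduction(ra: pd.DataFrame) -> int:
    """Apply the majority-detection rule to a relative-abundance matrix (percent)."""
    values = ra.set_index("mag_id") if "mag_id" in ra.columns else ra
    detected = values.astype(float) > 0.0
    cutoff = mfa_cutoff(values.shape[1])
    return int((detected.sum(axis=1) >= cutoff).sum())


def novelty_reproduction(identities: pd.DataFrame) -> dict[str, int]:
    """Apply the 16S novelty thresholds to per-genome best identities."""
    calls = [classify_16s_novelty(float(v)) for v in identities["best_identity"]]
    return {
        "novel_genus": sum(c == "novel_genus" for c in calls),
        "novel_species": sum(c == "novel_species" for c in calls),
    }


def gene_content_reproduction(gene_content: pd.DataFrame) -> dict[str, int]:
    """Pathway/marker counts from a long (mag_id, symbol) gene-content table.

    sox+rdsr co-occurrence here counts genomes with a complete sox cluster
    plus both dsrAB subunits; the published analysis additionally confirmed
    the oxidative orientation phylogenetically, which a gene-content table
    alone cannot re-derive.
    """
    for col in ("mag_id", "symbol"):
        if col not in gene_content.columns:
            raise SchemaError(f"gene content table missing column {col!r}")
    defs = {d.pathway_id: d for d in builtin_pathway_definitions()}
    genes_by_mag = {
        str(mag): frozenset(group["symbol"])
        for mag, group in gene_content.groupby("mag_id")
    }
    counts = {
        "sox_complete": 0,
        "sox_rdsr": 0,
        "denitrification_marker": 0,
        "dnra_marker": 0,
        "gs_gogat_complete": 0,
    }
    for genes in genes_by_mag.values():
        sox = pathway_completeness(genes, defs["sox"]).complete
        counts["sox_complete"] += sox
        counts["sox_rdsr"] += sox and {"dsrA", "dsrB"} <= genes
        counts["denitrification_marker"] += marker_call(genes, "denitrification")
        counts["dnra_marker"] += marker_call(genes, "dnra")
        counts["gs_gogat_complete"] += pathway_completeness(
            genes, defs["gs_gogat"]
        ).complete
    return counts


def cazy_total_reproduction(cazy_counts: pd.DataFrame) -> int:
    """Sum all numeric cells of a CAZyme gene-count table."""
    numeric = cazy_counts.select_dtypes("number")
    return int(numeric.to_numpy().sum())


def reproduce_all(directory: str | Path) -> dict:
    """Run every reproduction against the converted tables in ``directory``."""
    directory = Path(directory)
    missing = [f for f in EXPECTED_FILES.values() if not (directory / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"supplementary tables not found under {directory}: missing {missing}; "
            "see docs/supplementary.md for the retrieval and conversion recipe"
        )

    def read(name: str) -> pd.DataFrame:
        return pd.read_csv(directory / EXPECTED_FILES[name], sep="\t")

    out: dict = {}
    out["tiers"] = tier_count_reproduction(read("quality"))
    out["species_unclassified"] = species_unclassified_reproduction(read("taxonomy"))
    out["mfa"] = mfa_count_reproduction(read("relative_abundance"))
    out["novelty"] = novelty_reproduction(read("novelty_identity"))
    out.update(gene_content_reproduction(read("gene_content")))
    out["cazy_total"] = cazy_total_reproduction(read("cazy_counts"))
    return out
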