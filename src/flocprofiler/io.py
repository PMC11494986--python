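"""Domain types and tab-separated readers/writers for every table the pipeline touches.

All on-disk tables are UTF-8 TSV with a mandatory header row; ``.`` denotes a
missing value.  Readers validate strictly and report offending line numbers;
writers emit exactly what the readers accept, so write-then-read is the
identity on validated data.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import (
    DuplicateKeyError,
    SchemaError,
    TaxonomyParseError,
    ValidationError,
)

MISSING = "."

RRNA_GENES = frozenset({"5S", "16S", "23S"})

#: GTDB rank order, highest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

#: CAZy family pattern: class letters, family number, optional subfamily.
CAZY_PATTERN = re.compile(r"^(GH|GT|PL|CE|AA|CBM)(\d+)(?:_(\d+))?$")


# ---------------------------------------------------------------------------
# GenomeRecord
# ---------------------------------------------------------------------------


class GenomeRecord(BaseModel):
    """Per-MAG quality and structure metadata.

    ``completeness`` (C) and ``contamination`` (X) are CheckM2-style percent
    estimates; the quality score used for tiering is QS = C - 5X.
    """

    model_config = ConfigDict(frozen=True)

    mag_id: str
    completeness: float
    contamination: float
    genome_size: int
    n_contigs: int
    gc: float
    rrna_present: frozenset[str] = frozenset()
    trna_count: int = 0
    domain_label: str = "bacteria"

    @field_validator("mag_id")
    @classmethod
    def _nonempty_id(cls, v: str) -> str:
        if not v or v == MISSING:
            raise ValueError("mag_id must be a non-empty string")
        return v

    @field_validator("completeness")
    @classmethod
    def _completeness_range(cls, v: float) -> float:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"completeness {v} outside [0, 100]")
        return v

    @field_validator("contamination")
    @classmethod
    def _contamination_range(cls, v: float) -> float:
        if v < 0.0:
            raise ValueError(f"contamination {v} must be >= 0")
        return v

    @field_validator("gc")
    @classmethod
    def _gc_range(cls, v: float) -> float:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"GC {v} outside [0, 100]")
        return v

    @field_validator("genome_size", "n_contigs")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError(f"value {v} must be positive")
        return v

    @field_validator("trna_count")
    @classmethod
    def _nonnegative(cls, v: int) -> int:
        if v < 0:
            raise ValueError(f"tRNA count {v} must be >= 0")
        return v

    @field_validator("rrna_present", mode="before")
    @classmethod
    def _rrna_subset(cls, v):
        genes = frozenset(v)
        unknown = genes - RRNA_GENES
        if unknown:
            raise ValueError(f"unknown rRNA genes {sorted(unknown)}")
        return genes

    @field_validator("domain_label")
    @classmethod
    def _domain(cls, v: str) -> str:
        if v not in ("bacteria", "archaea"):
            raise ValueError(f"domain_label {v!r} not in {{bacteria, archaea}}")
        return v


_GENOME_COLUMNS = [
    "mag_id",
    "completeness",
    "contamination",
    "genome_size",
    "n_contigs",
    "gc",
    "rrna_present",
    "trna_count",
    "domain_label",
]


def read_genome_records(path: str | Path) -> list[GenomeRecord]:
    """Read a genome-record TSV into validated :class:`GenomeRecord` objects.

    Raises :class:`SchemaError` when required columns are absent and
    :class:`ValidationError` naming the record and line number when a row
    violates a bound (e.g. completeness above 100).
    """
    df = _read_tsv(path, _GENOME_COLUMNS)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            rec = GenomeRecord(
                mag_id=str(row["mag_id"]),
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                genome_size=int(row["genome_size"]),
                n_contigs=int(row["n_contigs"]),
                gc=float(row["gc"]),
                rrna_present=_parse_rrna(row["rrna_present"]),
                trna_count=int(row["trna_count"]),
                domain_label=str(row["domain_label"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"{path}: line {line_no} (mag_id={row['mag_id']!r}): {exc}"
            ) from exc
        if rec.mag_id in seen:
            raise DuplicateKeyError(
                f"{path}: duplicate mag_id {rec.mag_id!r} at line {line_no}",
                offenders=[rec.mag_id],
            )
        seen.add(rec.mag_id)
        records.append(rec)
    return records


def write_genome_records(records: Iterable[GenomeRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "mag_id": r.mag_id,
                "completeness": r.completeness,
                "contamination": r.contamination,
                "genome_size": r.genome_size,
                "n_contigs": r.n_contigs,
                "gc": r.gc,
                "rrna_present": ",".join(sorted(r.rrna_present)) or MISSING,
                "trna_count": r.trna_count,
                "domain_label": r.domain_label,
            }
        )
    pd.DataFrame(rows, columns=_GENOME_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_rrna(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    s = str(value).strip()
    if not s or s == MISSING:
        return frozenset()
    return frozenset(part.strip() for part in s.split(",") if part.strip())


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Taxonomy:
    """Seven GTDB rank labels; an empty label means unclassified at that rank.

    GTDB strings are prefix-closed: once a rank is unclassified every lower
    rank is unclassified too, and the constructor enforces this.
    """

    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self):
        labels = self.labels()
        seen_empty = False
        for rank, label in zip(RANKS, labels):
            if label == "":
                seen_empty = True
            elif seen_empty:
                raise TaxonomyParseError(
                    f"rank {rank!r} is labelled {label!r} below an unclassified rank"
                )

    def labels(self) -> tuple[str, ...]:
        return (
            self.domain,
            self.phylum,
            self.class_,
            self.order,
            self.family,
            self.genus,
            self.species,
        )

    def label_at(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.labels()[RANKS.index(rank)]

    def is_classified_at(self, rank: str) -> bool:
        return self.label_at(rank) != ""

    def to_string(self) -> str:
        return ";".join(p + l for p, l in zip(_RANK_PREFIXES, self.labels()))


def parse_taxonomy(gtdb_string: str) -> Taxonomy:
    """Parse a GTDB-style ``d__...;p__...;...;s__...`` string.

    Prefixes are stripped; an empty suffix (``g__``) yields an unclassified
    rank.  Raises :class:`TaxonomyParseError` on a wrong rank count, wrong
    prefix order, or a labelled rank below an unclassified one.
    """
    parts = [p.strip() for p in gtdb_string.strip().split(";")]
    if len(parts) != 7:
        raise TaxonomyParseError(
            f"expected 7 semicolon-separated ranks, got {len(parts)}: {gtdb_string!r}"
        )
    labels = []
    for part, prefix, rank in zip(parts, _RANK_PREFIXES, RANKS):
        if not part.startswith(prefix):
            raise TaxonomyParseError(
                f"rank {rank!r} must start with {prefix!r}, got {part!r}"
            )
        labels.append(part[len(prefix):])
    return Taxonomy(*labels)


def read_taxonomy_table(path: str | Path) -> dict[str, Taxonomy]:
    """Read a two-column (mag_id, taxonomy) TSV into a mapping."""
    df = _read_tsv(path, ["mag_id", "taxonomy"])
    out: dict[str, Taxonomy] = {}
    for i, row in df.iterrows():
        mag_id = str(row["mag_id"])
        if mag_id in out:
            raise DuplicateKeyError(
                f"{path}: duplicate mag_id {mag_id!r} at line {i + 2}",
                offenders=[mag_id],
            )
        raw = row["taxonomy"]
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            raw = ";".join(_RANK_PREFIXES)
        try:
            out[mag_id] = parse_taxonomy(str(raw))
        except TaxonomyParseError as exc:
            raise TaxonomyParseError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_taxonomy_table(taxonomies: Mapping[str, Taxonomy], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "mag_id": list(taxonomies),
            "taxonomy": [t.to_string() for t in taxonomies.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneTable
# ---------------------------------------------------------------------------

#: scope_id marking genes annotated on direct metagenome contigs rather than a MAG.
BULK_SCOPE = "bulk"

_GENE_COLUMNS = ["scope_id", "gene_id", "symbol", "ko_id", "cazy_family"]


@dataclass
class GeneTable:
    """Long-format gene annotations keyed by (scope_id, gene_id).

    ``scope_id`` is a MAG id or the literal ``bulk`` scope (optionally
    ``bulk:<sample>`` for per-sample metagenome contig annotations).  Rows
    whose symbol is absent from the controlled vocabulary are retained but
    flagged in ``unknown_symbol``.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _GENE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"gene table missing columns {missing}")
        if "unknown_symbol" not in self.frame.columns:
            self.frame = self.frame.assign(unknown_symbol=False)
        dup = self.frame.duplicated(subset=["scope_id", "gene_id"], keep=False)
        if dup.any():
            offenders = (
                self.frame.loc[dup, ["scope_id", "gene_id"]]
                .apply(tuple, axis=1)
                .unique()
                .tolist()
            )
            raise DuplicateKeyError(
                f"duplicate (scope_id, gene_id) keys: {offenders[:10]}"
                + ("..." if len(offenders) > 10 else ""),
                offenders=offenders,
            )
        bad = [
            fam
            for fam in self.frame["cazy_family"].dropna().unique()
            if fam != MISSING and not CAZY_PATTERN.match(str(fam))
        ]
        if bad:
            raise ValidationError(f"malformed CAZy families: {bad[:10]}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def symbols_for(self, scope_id: str) -> frozenset[str]:
        """Set of known (vocabulary) symbols annotated on one scope."""
        sub = self.frame[
            (self.frame["scope_id"] == scope_id) & (~self.frame["unknown_symbol"])
        ]
        return frozenset(sub["symbol"].dropna())

    def scopes(self) -> list[str]:
        return self.frame["scope_id"].unique().tolist()

    def cazy_rows(self) -> pd.DataFrame:
        mask = self.frame["cazy_family"].notna() & (self.frame["cazy_family"] != MISSING)
        return self.frame[mask]


def load_vocabulary(path: str | Path | None = None) -> frozenset[str]:
    """Load the controlled gene-symbol vocabulary (one symbol per line, ``#`` comments).

    With no path the vocabulary shipped with the package is used.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "vocabulary.txt"
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.add(line)
    return frozenset(symbols)


def read_gene_table(
    path: str | Path, vocabulary_path: str | Path | None = None
) -> GeneTable:
    """Read a long-format gene annotation TSV and flag out-of-vocabulary symbols."""
    df = _read_tsv(path, _GENE_COLUMNS)
    vocab = load_vocabulary(vocabulary_path)
    df["scope_id"] = df["scope_id"].astype(str)
    df["gene_id"] = df["gene_id"].astype(str)
    df["symbol"] = df["symbol"].astype(str)
    df["unknown_symbol"] = ~df["symbol"].isin(vocab)
    return GeneTable(df)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    out = table.frame[_GENE_COLUMNS].fillna(MISSING)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# AbundanceMatrix
# ---------------------------------------------------------------------------


@dataclass
class AbundanceMatrix:
    """MAG-by-sample mapped-read counts plus per-sample total PE read counts.

    Column sums of ``counts`` never exceed ``total_reads``: reads not mapped
    to any MAG are simply absent from the matrix.
    """

    counts: pd.DataFrame  # index: mag_ids, columns: sample_ids
    total_reads: pd.Series  # index: sample_ids

    def __post_init__(self):
        counts = self.counts
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise DuplicateKeyError("duplicate mag or sample ids in count matrix")
        if not counts.columns.equals(self.total_reads.index):
            self.total_reads = self.total_reads.reindex(counts.columns)
            if self.total_reads.isna().any():
                missing = self.total_reads[self.total_reads.isna()].index.tolist()
                raise SchemaError(f"samples missing total read counts: {missing}")
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative mapped counts")
        if (self.total_reads <= 0).any():
            bad = self.total_reads[self.total_reads <= 0].index.tolist()
            raise ValidationError(f"non-positive total reads for samples {bad}")
        over = counts.sum(axis=0) > self.total_reads
        if over.any():
            bad = over[over].index.tolist()
            raise ValidationError(
                f"mapped counts exceed total reads in samples {bad}"
            )

    @property
    def mag_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Percent relative abundance: 100 * mapped / total PE reads, per sample."""
        return 100.0 * self.counts.div(self.total_reads, axis=1)


def read_abundance_matrix(
    counts_path: str | Path, totals_path: str | Path
) -> AbundanceMatrix:
    """Read a counts TSV (first column ``mag_id``) and a (sample_id, total_reads) TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.name != "mag_id":
        raise SchemaError(
            f"{counts_path}: first column must be 'mag_id', got {counts.index.name!r}"
        )
    totals_df = _read_tsv(totals_path, ["sample_id", "total_reads"])
    totals = totals_df.set_index("sample_id")["total_reads"].astype(np.int64)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    totals.index = totals.index.astype(str)
    return AbundanceMatrix(counts.astype(np.int64), totals)


def write_abundance_matrix(
    matrix: AbundanceMatrix, counts_path: str | Path, totals_path: str | Path
) -> None:
    out = matrix.counts.copy()
    out.index.name = "mag_id"
    out.to_csv(counts_path, sep="\t")
    totals = matrix.total_reads.rename("total_reads")
    totals.index.name = "sample_id"
    totals.reset_index().to_csv(totals_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PathwayDefinition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayDefinition:
    """Ordered pathway steps; each step offers alternative gene complexes.

    A complex is a set of gene symbols that must ALL be present; a step is
    satisfied when any one of its alternative complexes is complete.
    """

    pathway_id: str
    name: str
    steps: tuple[tuple[frozenset[str], ...], ...]
    marker_symbols: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.steps:
            raise ValidationError(f"pathway {self.pathway_id!r} has no steps")
        for i, step in enumerate(self.steps):
            if not step:
                raise ValidationError(
                    f"pathway {self.pathway_id!r} step {i} has no alternatives"
                )
            for alt in step:
                if not alt:
                    raise ValidationError(
                        f"pathway {self.pathway_id!r} step {i} has an empty complex"
                    )
        extra = self.marker_symbols - self.symbol_union()
        if extra:
            raise ValidationError(
                f"pathway {self.pathway_id!r} markers {sorted(extra)} not in any step"
            )

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def symbol_union(self) -> frozenset[str]:
        out: set[str] = set()
        for step in self.steps:
            for alt in step:
                out |= alt
        return frozenset(out)


def _definition_from_dict(d: Mapping) -> PathwayDefinition:
    steps = tuple(
        tuple(frozenset(alt) for alt in step) for step in d["steps"]
    )
    return PathwayDefinition(
        pathway_id=d["pathway_id"],
        name=d.get("name", d["pathway_id"]),
        steps=steps,
        marker_symbols=frozenset(d.get("marker_symbols", [])),
    )


def read_pathway_definitions(path: str | Path) -> list[PathwayDefinition]:
    """Load pathway definitions from a JSON or YAML config file.

    The file holds a list of objects with ``pathway_id``, optional ``name``,
    ``steps`` (list of steps, each a list of alternative complexes, each a
    list of symbols) and optional ``marker_symbols``.
    """
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, list):
        raise SchemaError(f"{path}: expected a list of pathway definitions")
    return [_definition_from_dict(d) for d in raw]


def write_pathway_definitions(
    definitions: Sequence[PathwayDefinition], path: str | Path
) -> None:
    raw = [
        {
            "pathway_id": d.pathway_id,
            "name": d.name,
            "steps": [[sorted(alt) for alt in step] for step in d.steps],
            "marker_symbols": sorted(d.marker_symbols),
        }
        for d in definitions
    ]
    Path(path).write_text(json.dumps(raw, indent=2) + "\n")


# ---------------------------------------------------------------------------
# SimilarityRecord
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityRecord:
    """One best-hit row of a pairwise similarity table (alignment output)."""

    query_id: str
    reference_id: str
    reference_label: str
    percent_identity: float
    alignment_length: int

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length <= 0:
            raise ValidationError(
                f"alignment length {self.alignment_length} must be positive"
            )


_SIMILARITY_COLUMNS = [
    "query_id",
    "reference_id",
    "reference_label",
    "percent_identity",
    "alignment_length",
]

_BLAST_OUTFMT6 = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_similarity_table(
    path: str | Path, label_map: Mapping[str, str] | None = None
) -> list[SimilarityRecord]:
    """Read a similarity table in the package's 5-column dialect.

    Keeps only the best (highest-identity) hit per (query, reference) pair.
    """
    df = _read_tsv(path, _SIMILARITY_COLUMNS)
    df = df.assign(
        percent_identity=df["percent_identity"].astype(float),
        alignment_length=df["alignment_length"].astype(int),
    )
    return _best_hits(df)


def read_blast_tabular(
    path: str | Path, label_map: Mapping[str, str]
) -> list[SimilarityRecord]:
    """Read 12-column tabular alignment output (qseqid sseqid pident ...).

    ``label_map`` assigns each reference (subject) id a free-text label such
    as a taxon name or a ``reductive``/``oxidative`` orientation; unmapped
    subjects are labelled with the subject id itself.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_BLAST_OUTFMT6)
    out = pd.DataFrame(
        {
            "query_id": df["qseqid"].astype(str),
            "reference_id": df["sseqid"].astype(str),
            "reference_label": [
                label_map.get(str(s), str(s)) for s in df["sseqid"]
            ],
            "percent_identity": df["pident"].astype(float),
            "alignment_length": df["length"].astype(int),
        }
    )
    return _best_hits(out)


def _best_hits(df: pd.DataFrame) -> list[SimilarityRecord]:
    df = (
        df.sort_values("percent_identity", ascending=False)
        .drop_duplicates(subset=["query_id", "reference_id"], keep="first")
        .sort_index()
    )
    return [
        SimilarityRecord(
            query_id=str(r.query_id),
            reference_id=str(r.reference_id),
            reference_label=str(r.reference_label),
            percent_identity=float(r.percent_identity),
            alignment_length=int(r.alignment_length),
        )
        for r in df.itertuples(index=False)
    ]


def write_similarity_table(
    records: Iterable[SimilarityRecord], path: str | Path
) -> None:
    rows = [
        {
            "query_id": r.query_id,
            "reference_id": r.reference_id,
            "reference_label": r.reference_label,
            "percent_identity": r.percent_identity,
            "alignment_length": r.alignment_length,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_SIMILARITY_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# optional 16S FASTA intake
# ---------------------------------------------------------------------------

_SIXTEEN_S_ID = re.compile(r"^(?P<mag>.+?)_16S(?:_\d+)?$")


def read_16s_fasta(path: str | Path, min_length: int = 1000) -> dict[str, str]:
    """Read per-MAG 16S rRNA sequences from FASTA, keyed by MAG id.

    Record ids must be ``<mag_id>_16S`` (optionally with a numeric counter
    suffix); sequences shorter than ``min_length`` nucleotides are dropped,
    matching the usual near-full-length requirement for novelty screening.
    Only the longest sequence per MAG is kept.
    """
    from Bio import SeqIO

    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        m = _SIXTEEN_S_ID.match(record.id)
        if not m:
            raise ValidationError(
                f"{path}: FASTA id {record.id!r} is not '<mag_id>_16S[_<n>]'"
            )
        seq = str(record.seq)
        if len(seq) < min_length:
            continue
        mag = m.group("mag")
        if mag not in out or len(seq) > len(out[mag]):
            out[mag] = seq
    return out


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype=object,
            na_values=[MISSING],
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected a header row") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df = df.where(pd.notna(df), None)
    return df
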