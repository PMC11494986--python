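"""Pathway-completeness rule engine and nitrogen/sulfur marker calls.

A pathway is an ordered list of steps; each step lists alternative gene
complexes (sets of subunit symbols).  A step is satisfied when any one
alternative has ALL of its subunits present, and completeness is the
unweighted fraction of satisfied steps.  This is the grammar behind the
slashed gene-set shorthand used for denitrification (napAB/narGHI, nirS/nirK,
norBC, nosZ), DNRA (nirBD/nrfAH), the sox cluster (soxXAYZBCD), and the
ammonium-assimilation pathways (GS-GOGAT: glnA + gltB + gltD; GDH: gdh).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .io import GeneTable, PathwayDefinition


@dataclass(frozen=True)
class PathwayCall:
    """Completeness of one pathway in one genome (or bulk) scope."""

    scope_id: str
    pathway_id: str
    completeness_fraction: float
    complete: bool
    satisfied_steps: frozenset[int]
    marker_hit: bool


def _step_satisfied(genes: frozenset[str], step: Sequence[frozenset[str]]) -> bool:
    return any(alt <= genes for alt in step)


def pathway_completeness(
    genes: Iterable[str], definition: PathwayDefinition, scope_id: str = ""
) -> PathwayCall:
    """Evaluate one pathway against a genome's gene-symbol set."""
    gene_set = frozenset(genes)
    satisfied = frozenset(
        i for i, step in enumerate(definition.steps) if _step_satisfied(gene_set, step)
    )
    fraction = len(satisfied) / definition.n_steps
    return PathwayCall(
        scope_id=scope_id,
        pathway_id=definition.pathway_id,
        completeness_fraction=fraction,
        complete=len(satisfied) == definition.n_steps,
        satisfied_steps=satisfied,
        marker_hit=bool(definition.marker_symbols & gene_set)
        if definition.marker_symbols
        else False,
    )


def call_pathways(
    gene_table: GeneTable,
    definitions: Sequence[PathwayDefinition],
    scopes: Sequence[str] | None = None,
) -> list[PathwayCall]:
    """Evaluate every definition for every scope in a gene table."""
    if scopes is None:
        scopes = gene_table.scopes()
    known = gene_table.frame[~gene_table.frame["unknown_symbol"]]
    by_scope = {
        scope: frozenset(group["symbol"].dropna())
        for scope, group in known.groupby("scope_id")
    }
    calls = []
    for scope in scopes:
        genes = by_scope.get(scope, frozenset())
        for definition in definitions:
            calls.append(pathway_completeness(genes, definition, scope_id=scope))
    return calls


def calls_frame(calls: Sequence[PathwayCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scope_id": [c.scope_id for c in calls],
            "pathway_id": [c.pathway_id for c in calls],
            "completeness_fraction": [c.completeness_fraction for c in calls],
            "complete": [c.complete for c in calls],
            "satisfied_steps": [
                ",".join(map(str, sorted(c.satisfied_steps))) for c in calls
            ],
            "marker_hit": [c.marker_hit for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# Built-in pathway definitions
# ---------------------------------------------------------------------------


def builtin_pathway_definitions() -> list[PathwayDefinition]:
    """The nitrogen- and sulfur-cycle pathway set shipped with the package.

    Nitrate reduction to nitrite accepts the periplasmic (napAB) or the
    membrane-bound (narGHI) reductase; NO-forming nitrite reduction accepts
    nirS or nirK.  Collapsed symbols (nas, nirA, hao, nxr, hzs, hdh, nif,
    gdh) stand for whole enzyme systems whose subunit granularity varies
    between annotation tools.  The oxidative-vs-reductive orientation of
    dsrAB is resolved separately (see :mod:`flocprofiler.screening`) before
    rdsr or the reductive sulfate-reduction pathway is credited.
    """
    nitrate_to_nitrite = (
        frozenset({"napA", "napB"}),
        frozenset({"narG", "narH", "narI"}),
    )
    defs = [
        PathwayDefinition(
            "denitrification",
            "Denitrification (NO3- -> N2)",
            steps=(
                nitrate_to_nitrite,
                (frozenset({"nirS"}), frozenset({"nirK"})),
                (frozenset({"norB", "norC"}),),
                (frozenset({"nosZ"}),),
            ),
            marker_symbols=frozenset({"nirS", "nirK"}),
        ),
        PathwayDefinition(
            "dnra",
            "Dissimilatory nitrate reduction to ammonia",
            steps=(
                nitrate_to_nitrite,
                (frozenset({"nirB", "nirD"}), frozenset({"nrfA", "nrfH"})),
            ),
            marker_symbols=frozenset({"nirB", "nirD"}),
        ),
        PathwayDefinition(
            "assimilatory_nitrate_reduction",
            "Assimilatory nitrate reduction",
            steps=((frozenset({"nas"}),), (frozenset({"nirA"}),)),
        ),
        PathwayDefinition(
            "autotrophic_nitrification",
            "Autotrophic nitrification (NH3 -> NO3-)",
            steps=(
                (frozenset({"amoA", "amoB", "amoC"}),),
                (frozenset({"hao"}),),
                (frozenset({"nxr"}),),
            ),
        ),
        PathwayDefinition(
            "anammox",
            "Anaerobic ammonium oxidation",
            steps=((frozenset({"hzs"}),), (frozenset({"hdh"}),)),
        ),
        PathwayDefinition(
            "nitrogen_fixation",
            "Nitrogen fixation",
            steps=((frozenset({"nif"}),),),
        ),
        PathwayDefinition(
            "gs_gogat",
            "Ammonium assimilation via GS-GOGAT",
            steps=((frozenset({"glnA"}),), (frozenset({"gltB", "gltD"}),)),
        ),
        PathwayDefinition(
            "gdh",
            "Ammonium assimilation via glutamate dehydrogenase",
            steps=((frozenset({"gdh"}),),),
        ),
        PathwayDefinition(
            "sox",
            "Thiosulfate/sulfide oxidation (sox cluster)",
            steps=(
                (frozenset({"soxX", "soxA", "soxY", "soxZ", "soxB", "soxC", "soxD"}),),
            ),
            marker_symbols=frozenset({"soxB"}),
        ),
        PathwayDefinition(
            "rdsr",
            "Reverse (oxidative) dissimilatory sulfite reduction",
            steps=((frozenset({"dsrA", "dsrB"}),),),
        ),
        PathwayDefinition(
            "sulfate_reduction",
            "Reductive dissimilatory sulfate reduction",
            steps=(
                (frozenset({"sat"}),),
                (frozenset({"aprA", "aprB"}),),
                (frozenset({"dsrA", "dsrB"}),),
            ),
        ),
    ]
    return defs


def get_definition(pathway_id: str) -> PathwayDefinition:
    for d in builtin_pathway_definitions():
        if d.pathway_id == pathway_id:
            return d
    raise KeyError(pathway_id)


# ---------------------------------------------------------------------------
# Marker calls and derived classifications
# ---------------------------------------------------------------------------

#: Marker rules: denitrification by NO-forming nitrite reductase (nirS OR
#: nirK); DNRA by the NADH nitrite reductase complex (nirB AND nirD); sulfur
#: oxidation by soxB.
_MARKER_RULES = {
    "denitrification": [frozenset({"nirS"}), frozenset({"nirK"})],
    "dnra": [frozenset({"nirB", "nirD"})],
    "sox_oxidation": [frozenset({"soxB"})],
}


def marker_call(genes: Iterable[str], process: str) -> bool:
    """Process-marker presence call for one genome's gene-symbol set."""
    if process not in _MARKER_RULES:
        raise ValidationError(
            f"unknown process {process!r}; expected one of {sorted(_MARKER_RULES)}"
        )
    gene_set = frozenset(genes)
    return any(alt <= gene_set for alt in _MARKER_RULES[process])


AEROBIC_CAPABLE = "aerobic_capable"
ANAEROBIC_ONLY = "anaerobic_only"
NO_NITRATE_REDUCTASE = "none"


def denitrifier_mode(genes: Iterable[str]) -> str:
    """Classify nitrate-reductase repertoire into aerobic-capable vs anaerobic-only.

    The periplasmic reductase napAB is expressed under both aerobic and
    anaerobic conditions, so a complete napAB marks an aerobic-capable
    denitrifier; a complete membrane-bound narGHI without napAB marks an
    anaerobic-only one.
    """
    gene_set = frozenset(genes)
    if {"napA", "napB"} <= gene_set:
        return AEROBIC_CAPABLE
    if {"narG", "narH", "narI"} <= gene_set:
        return ANAEROBIC_ONLY
    return NO_NITRATE_REDUCTASE


def apply_dsrab_orientation(
    calls: Sequence[PathwayCall],
    orientation: Mapping[str, str],
) -> list[PathwayCall]:
    """Gate direction-sensitive dsrAB pathways on the per-genome orientation.

    The rdsr pathway is only credited when the genome's dsrAB is oxidative,
    and the dsrAB step of reductive sulfate reduction only when it is
    reductive; a genome absent from ``orientation`` (or ambiguous) gets
    neither.  Direction-insensitive pathways pass through unchanged.
    """
    out: list[PathwayCall] = []
    for c in calls:
        label = orientation.get(c.scope_id)
        if c.pathway_id == "rdsr" and label != "oxidative":
            out.append(_without_step(c, 0, n_steps=1))
        elif c.pathway_id == "sulfate_reduction" and label != "reductive":
            out.append(_without_step(c, 2, n_steps=3))
        else:
            out.append(c)
    return out


def _without_step(call: PathwayCall, step_index: int, n_steps: int) -> PathwayCall:
    satisfied = frozenset(call.satisfied_steps - {step_index})
    return PathwayCall(
        scope_id=call.scope_id,
        pathway_id=call.pathway_id,
        completeness_fraction=len(satisfied) / n_steps,
        complete=len(satisfied) == n_steps,
        satisfied_steps=satisfied,
        marker_hit=call.marker_hit,
    )


def sox_rdsr_cooccurrence(
    calls: Sequence[PathwayCall],
    dsrab_orientation: Mapping[str, str],
) -> set[str]:
    """MAGs with a complete sox cluster AND oxidative dsrAB.

    ``dsrab_orientation`` maps scope id to reductive/oxidative/ambiguous
    (from :func:`flocprofiler.screening.classify_dsrab`); rdsr is only
    credited when the orientation is oxidative.
    """
    sox_complete = {c.scope_id for c in calls if c.pathway_id == "sox" and c.complete}
    rdsr_present = {c.scope_id for c in calls if c.pathway_id == "rdsr" and c.complete}
    oxidative = {
        scope for scope, label in dsrab_orientation.items() if label == "oxidative"
    }
    return sox_complete & rdsr_present & oxidative


# ---------------------------------------------------------------------------
# Bulk pathway x sample gene-abundance matrix
# ---------------------------------------------------------------------------


def pathway_abundance_matrix(
    bulk_genes: pd.DataFrame,
    definitions: Sequence[PathwayDefinition],
    zscore: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Pathway-by-sample gene counts from per-sample bulk annotations, z-scored by row.

    ``bulk_genes`` holds one row per annotated bulk gene with columns
    ``sample_id`` and ``symbol``.  A raw cell counts the genes whose symbol
    belongs to the pathway's symbol union; each row is then transformed to
    (x - row mean) / row standard deviation (population SD).  Constant rows
    map to all-zero and are returned in the flagged list.  With fewer than
    two samples z-scoring is refused and raw counts are returned with the
    flag list ``['zscore_refused']``.
    """
    for col in ("sample_id", "symbol"):
        if col not in bulk_genes.columns:
            raise ValidationError(f"bulk gene table missing column {col!r}")
    samples = sorted(bulk_genes["sample_id"].unique())
    raw = pd.DataFrame(
        0, index=[d.pathway_id for d in definitions], columns=samples, dtype=float
    )
    grouped = bulk_genes.groupby("sample_id")["symbol"]
    per_sample_symbols = {s: g for s, g in grouped}
    for d in definitions:
        union = d.symbol_union()
        for s in samples:
            raw.loc[d.pathway_id, s] = per_sample_symbols[s].isin(union).sum()
    raw.index.name = "pathway_id"
    raw.columns.name = "sample_id"
    if not zscore:
        return raw, []
    if len(samples) < 2:
        return raw, ["zscore_refused"]
    values = raw.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, keepdims=True)  # population SD
    constant = sds[:, 0] == 0
    sds[constant] = 1.0
    z = (values - means) / sds
    z[constant] = 0.0
    flagged = [str(p) for p, c in zip(raw.index, constant) if c]
    return pd.DataFrame(z, index=raw.index, columns=raw.columns), flagged
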