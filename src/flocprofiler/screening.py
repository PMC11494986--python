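"""Similarity-table classifications: dsrAB orientation, HN-AD marker
screening, and 16S rRNA novelty calls.

These operations consume pairwise alignment results (best hits as
:class:`~flocprofiler.io.SimilarityRecord` rows); the alignments themselves
are produced upstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .io import SimilarityRecord

REDUCTIVE = "reductive"
OXIDATIVE = "oxidative"
AMBIGUOUS = "ambiguous"

NOVEL_GENUS = "novel_genus"
NOVEL_SPECIES = "novel_species"
KNOWN_SPECIES = "known_species"

#: 16S rRNA identity thresholds: below GENUS_IDENTITY the query represents a
#: new genus; between the two, a new species; at or above SPECIES_IDENTITY a
#: known species.
GENUS_IDENTITY_THRESHOLD = 94.5
SPECIES_IDENTITY_THRESHOLD = 98.7

#: HN-AD marker proteins: the dinitrogen-forming complex DnfABC (all three
#: subunits required) or pyruvic oxime dioxygenase (POD) alone.
HNAD_MARKERS = ("DnfA", "DnfB", "DnfC", "POD")


# ---------------------------------------------------------------------------
# dsrAB orientation
# ---------------------------------------------------------------------------


def classify_dsrab(
    records: Iterable[SimilarityRecord], margin: float = 2.0
) -> dict[str, str]:
    """Assign each query the orientation of its nearest labelled reference.

    References carry ``reductive`` or ``oxidative`` labels; a query whose
    best reductive and best oxidative identities lie within ``margin``
    percentage points of each other is called ``ambiguous``, as is a query
    with no labelled hits.
    """
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    best: dict[str, dict[str, float]] = defaultdict(dict)
    queries: set[str] = set()
    for rec in records:
        queries.add(rec.query_id)
        label = rec.reference_label
        if label not in (REDUCTIVE, OXIDATIVE):
            continue
        cur = best[rec.query_id].get(label, float("-inf"))
        if rec.percent_identity > cur:
            best[rec.query_id][label] = rec.percent_identity
    out: dict[str, str] = {}
    for q in queries:
        hits = best.get(q, {})
        if not hits:
            out[q] = AMBIGUOUS
            continue
        red = hits.get(REDUCTIVE, float("-inf"))
        oxi = hits.get(OXIDATIVE, float("-inf"))
        if abs(red - oxi) <= margin and len(hits) == 2:
            out[q] = AMBIGUOUS
        else:
            out[q] = REDUCTIVE if red > oxi else OXIDATIVE
    return out


# ---------------------------------------------------------------------------
# HN-AD screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenResult:
    """Per-MAG heterotrophic nitrification-aerobic denitrification screen.

    Positive iff all three DnfABC subunits, or POD alone, pass both the
    identity and coverage thresholds; per-marker best identities are always
    reported so the decision can be reproduced from the stored values.
    """

    mag_id: str
    marker_identity: Mapping[str, float] = field(default_factory=dict)
    marker_coverage: Mapping[str, float] = field(default_factory=dict)
    positive: bool = False


def screen_hnad(
    records: Iterable[SimilarityRecord],
    marker_lengths: Mapping[str, int],
    identity_threshold: float = 60.0,
    coverage_threshold: float = 70.0,
) -> dict[str, ScreenResult]:
    """Screen MAGs for the HN-AD marker enzymes DnfABC and POD.

    ``records`` hold per-MAG best hits against the four marker proteins
    (reference_label names the marker); ``marker_lengths`` gives each
    marker's reference protein length, against which alignment-length
    coverage (percent) is computed.
    """
    unknown = set(marker_lengths) - set(HNAD_MARKERS)
    if unknown:
        raise ValidationError(f"unknown HN-AD markers: {sorted(unknown)}")
    identities: dict[str, dict[str, float]] = defaultdict(dict)
    coverages: dict[str, dict[str, float]] = defaultdict(dict)
    for rec in records:
        marker = rec.reference_label
        if marker not in HNAD_MARKERS:
            continue
        if marker not in marker_lengths:
            raise ValidationError(f"no reference length for marker {marker!r}")
        cov = 100.0 * rec.alignment_length / marker_lengths[marker]
        if rec.percent_identity > identities[rec.query_id].get(marker, -1.0):
            identities[rec.query_id][marker] = rec.percent_identity
            coverages[rec.query_id][marker] = cov

    def passes(mag: str, marker: str) -> bool:
        return (
            identities[mag].get(marker, 0.0) >= identity_threshold
            and coverages[mag].get(marker, 0.0) >= coverage_threshold
        )

    out = {}
    for mag in identities:
        dnf = all(passes(mag, m) for m in ("DnfA", "DnfB", "DnfC"))
        pod = passes(mag, "POD")
        out[mag] = ScreenResult(
            mag_id=mag,
            marker_identity=dict(identities[mag]),
            marker_coverage=dict(coverages[mag]),
            positive=dnf or pod,
        )
    return out


# ---------------------------------------------------------------------------
# 16S novelty
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoveltyCall:
    mag_id: str
    best_identity: float
    call: str


def classify_16s_novelty(best_identity: float) -> str:
    """Three-way novelty call from the best 16S identity against references.

    The boundaries are assigned by strict-less-than: identity exactly 94.5
    is a novel species, exactly 98.7 a known species.
    """
    if not 0.0 <= best_identity <= 100.0:
        raise ValidationError(f"identity {best_identity} outside [0, 100]")
    if best_identity < GENUS_IDENTITY_THRESHOLD:
        return NOVEL_GENUS
    if best_identity < SPECIES_IDENTITY_THRESHOLD:
        return NOVEL_SPECIES
    return KNOWN_SPECIES


def novelty_calls(
    records: Iterable[SimilarityRecord],
) -> dict[str, NoveltyCall]:
    """Best-hit novelty call per query from a 16S similarity table."""
    best: dict[str, float] = {}
    for rec in records:
        if rec.percent_identity > best.get(rec.query_id, -1.0):
            best[rec.query_id] = rec.percent_identity
    return {
        q: NoveltyCall(mag_id=q, best_identity=i, call=classify_16s_novelty(i))
        for q, i in best.items()
    }


def novelty_counts(calls: Mapping[str, NoveltyCall] | Sequence[NoveltyCall]) -> dict[str, int]:
    if isinstance(calls, Mapping):
        calls = list(calls.values())
    out = {NOVEL_GENUS: 0, NOVEL_SPECIES: 0, KNOWN_SPECIES: 0}
    for c in calls:
        out[c.call] += 1
    return out
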