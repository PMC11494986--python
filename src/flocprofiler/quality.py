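"""MAG quality scoring, quality tiers, MIMAG high-quality flagging, and
unclassified-rank tallies.

The quality score is QS = C - 5X, with completeness C and contamination X in
percent.  Tiers follow the common MAG-reporting convention: high quality
needs C >= 90 and X <= 5; medium quality needs C >= 50 and X < 10; anything
else fails.  A high-quality MAG additionally meets the MIMAG high-quality
standard when it carries all three rRNA genes (5S, 16S, 23S) and at least 18
tRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .io import RANKS, RRNA_GENES, GenomeRecord, Taxonomy

TIER_HIGH = "high"
TIER_MEDIUM = "medium"
TIER_FAIL = "fail"


@dataclass(frozen=True)
class TierThresholds:
    """Completeness/contamination bounds for the two quality tiers.

    The medium-quality contamination bound is strict (X < 10) by default; set
    ``medium_contamination_inclusive`` to accept X = 10.  ``mimag_min_trna``
    defaults to the MIMAG standard's 18; set 19 for a strictly-more-than-18
    reading.
    """

    high_completeness: float = 90.0
    high_contamination: float = 5.0
    medium_completeness: float = 50.0
    medium_contamination: float = 10.0
    medium_contamination_inclusive: bool = False
    mimag_min_trna: int = 18


DEFAULT_THRESHOLDS = TierThresholds()


@dataclass(frozen=True)
class QualityAssessment:
    mag_id: str
    quality_score: float
    tier: str
    mimag_high: bool


def _check_range(completeness: float, contamination: float) -> None:
    if not 0.0 <= completeness <= 100.0:
        raise ValidationError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0.0:
        raise ValidationError(f"contamination {contamination} must be >= 0")


def quality_score(completeness: float, contamination: float) -> float:
    """QS = C - 5X: completeness minus five times contamination (percent)."""
    _check_range(completeness, contamination)
    return completeness - 5.0 * contamination


def classify_tier(
    completeness: float,
    contamination: float,
    thresholds: TierThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Assign one of {high, medium, fail}; high is tested first, so tiers are exclusive."""
    _check_range(completeness, contamination)
    t = thresholds
    if completeness >= t.high_completeness and contamination <= t.high_contamination:
        return TIER_HIGH
    within_x = (
        contamination <= t.medium_contamination
        if t.medium_contamination_inclusive
        else contamination < t.medium_contamination
    )
    if completeness >= t.medium_completeness and within_x:
        return TIER_MEDIUM
    return TIER_FAIL


def mimag_high_flag(
    record: GenomeRecord, tier: str, thresholds: TierThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """True iff the MAG is high tier, carries 5S+16S+23S, and has >= the tRNA minimum."""
    return (
        tier == TIER_HIGH
        and record.rrna_present == RRNA_GENES
        and record.trna_count >= thresholds.mimag_min_trna
    )


def assess(
    records: Iterable[GenomeRecord],
    thresholds: TierThresholds = DEFAULT_THRESHOLDS,
) -> list[QualityAssessment]:
    """Score and tier a collection of genome records."""
    out = []
    for rec in records:
        tier = classify_tier(rec.completeness, rec.contamination, thresholds)
        out.append(
            QualityAssessment(
                mag_id=rec.mag_id,
                quality_score=quality_score(rec.completeness, rec.contamination),
                tier=tier,
                mimag_high=mimag_high_flag(rec, tier, thresholds),
            )
        )
    return out


def assessment_frame(assessments: Sequence[QualityAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mag_id": [a.mag_id for a in assessments],
            "quality_score": [a.quality_score for a in assessments],
            "tier": [a.tier for a in assessments],
            "mimag_high": [a.mimag_high for a in assessments],
        }
    )


def tier_counts(assessments: Sequence[QualityAssessment]) -> dict[str, int]:
    """Summary counts: per-tier totals plus the MIMAG high-quality subset."""
    counts = {TIER_HIGH: 0, TIER_MEDIUM: 0, TIER_FAIL: 0, "mimag_high": 0}
    for a in assessments:
        counts[a.tier] += 1
        if a.mimag_high:
            counts["mimag_high"] += 1
    return counts


def count_unclassified(
    taxonomies: Iterable[Taxonomy] | Mapping[str, Taxonomy], rank: str
) -> int:
    """Number of taxonomies with an empty label at ``rank``."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if isinstance(taxonomies, Mapping):
        taxonomies = taxonomies.values()
    return sum(1 for t in taxonomies if not t.is_classified_at(rank))
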