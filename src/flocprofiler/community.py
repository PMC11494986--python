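"""Relative abundance, detection frequency, core-microbiota selection and
mapping-rate summaries for a MAG-by-sample count matrix.

A MAG is "most frequently appeared" (MfA) when it is detected in more than
half of the samples — with 11 metagenomes, in at least 6 — and "least
frequently appeared" (LfA) otherwise.  Core members are the MfA MAGs whose
mean relative abundance over all samples exceeds 0.01%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import ValidationError
from .io import AbundanceMatrix, Taxonomy

MFA = "MfA"
LFA = "LfA"

#: Core-membership mean relative-abundance threshold, percent.
CORE_MEAN_RA_THRESHOLD = 0.01

#: Sentinel taxon label for MAGs unclassified at the aggregation rank.
UNCLASSIFIED_LABEL = "unclassified"


def relative_abundance(mapped: int, total: int) -> float:
    """Percent of a sample's total PE reads mapped to one MAG."""
    if total <= 0:
        raise ValidationError(f"total reads must be positive, got {total}")
    if mapped < 0:
        raise ValidationError(f"mapped reads must be >= 0, got {mapped}")
    if mapped > total:
        raise ValidationError(f"mapped reads {mapped} exceed total reads {total}")
    return 100.0 * mapped / total


def mfa_cutoff(n_samples: int) -> int:
    """Smallest detection count that is a strict majority of samples: floor(n/2)+1."""
    if n_samples < 1:
        raise ValidationError(f"need at least one sample, got {n_samples}")
    return n_samples // 2 + 1


@dataclass
class CommunityProfile:
    """Per-MAG community membership summary derived from a count matrix."""

    relative_abundances: pd.DataFrame  # MAG x sample, percent
    frame: pd.DataFrame  # per-MAG: detection_frequency, frequency_category, mean_RA, core
    detection_threshold: float
    core_threshold: float

    @property
    def mag_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def core_set(self) -> set[str]:
        return set(self.frame.index[self.frame["core"]])

    def category_counts(self) -> dict[str, int]:
        counts = self.frame["frequency_category"].value_counts().to_dict()
        return {MFA: counts.get(MFA, 0), LFA: counts.get(LFA, 0)}


def build_profile(
    matrix: AbundanceMatrix,
    detection_threshold: float = 0.0,
    core_threshold: float = CORE_MEAN_RA_THRESHOLD,
    mean_over_detected_only: bool = False,
) -> CommunityProfile:
    """Classify every MAG as MfA/LfA and select core members.

    Detection in a sample means relative abundance strictly above
    ``detection_threshold`` (percent; default 0, i.e. any mapped read).  The
    mean relative abundance is taken over ALL samples by default; set
    ``mean_over_detected_only`` to average only over samples where the MAG
    was detected.
    """
    if detection_threshold < 0:
        raise ValidationError("detection threshold must be >= 0")
    ra = matrix.relative_abundance()
    detected = ra > detection_threshold
    freq = detected.sum(axis=1).astype(int)
    cutoff = mfa_cutoff(matrix.n_samples)
    category = freq.map(lambda f: MFA if f >= cutoff else LFA)
    if mean_over_detected_only:
        mean_ra = ra.where(detected).mean(axis=1).fillna(0.0)
    else:
        mean_ra = ra.mean(axis=1)
    core = (category == MFA) & (mean_ra > core_threshold)
    frame = pd.DataFrame(
        {
            "detection_frequency": freq,
            "frequency_category": category,
            "mean_RA": mean_ra,
            "core": core,
        }
    )
    frame.index.name = "mag_id"
    return CommunityProfile(
        relative_abundances=ra,
        frame=frame,
        detection_threshold=detection_threshold,
        core_threshold=core_threshold,
    )


def classify_frequency(
    matrix: AbundanceMatrix, detection_threshold: float = 0.0
) -> pd.Series:
    """Per-MAG MfA/LfA category (see :func:`build_profile`)."""
    return build_profile(matrix, detection_threshold).frame["frequency_category"]


def core_members(profile: CommunityProfile) -> set[str]:
    """MAG ids that are MfA with mean relative abundance above the core threshold."""
    return profile.core_set()


def mapping_rate(
    matrix: AbundanceMatrix, sample_groups: Mapping[str, str] | None = None
) -> tuple[pd.Series, dict[str, float]]:
    """Per-sample percent of total reads mapped to any MAG, plus group means.

    ``sample_groups`` maps sample id to a group name (e.g. biofloc, rearing
    water, shrimp intestine, marine biofilm); with ``None`` every sample goes
    into one group ``all``.
    """
    per_sample = 100.0 * matrix.counts.sum(axis=0) / matrix.total_reads
    if sample_groups is None:
        sample_groups = {s: "all" for s in matrix.sample_ids}
    unknown = set(sample_groups) - set(matrix.sample_ids)
    if unknown:
        raise ValidationError(f"unknown samples in grouping: {sorted(unknown)}")
    group_means: dict[str, float] = {}
    groups = pd.Series(sample_groups)
    for group, samples in groups.groupby(groups).groups.items():
        group_means[str(group)] = float(per_sample[list(samples)].mean())
    return per_sample, group_means


def aggregate_by_taxon(
    profile: CommunityProfile,
    taxonomies: Mapping[str, Taxonomy],
    rank: str,
) -> pd.DataFrame:
    """Per-taxon MAG counts and summed mean relative abundance at one rank.

    Every MAG must have a taxonomy; MAGs unclassified at ``rank`` are grouped
    under the ``unclassified`` sentinel, so counts always partition the MAG
    set.
    """
    missing = [m for m in profile.mag_ids if m not in taxonomies]
    if missing:
        raise ValidationError(f"MAGs without taxonomy: {missing[:10]}")
    labels = {
        m: (taxonomies[m].label_at(rank) or UNCLASSIFIED_LABEL)
        for m in profile.mag_ids
    }
    frame = profile.frame.assign(taxon=pd.Series(labels))
    out = frame.groupby("taxon").agg(
        n_mags=("taxon", "size"),
        summed_mean_RA=("mean_RA", "sum"),
        n_core=("core", "sum"),
    )
    out["n_core"] = out["n_core"].astype(int)
    return out.sort_values("n_mags", ascending=False)
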