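"""Relative abundance, MfA/LfA classification, core selection, mapping rates."""

import numpy as np
import pandas as pd
import pytest

from flocprofiler import (
    AbundanceMatrix,
    ValidationError,
    aggregate_by_taxon,
    build_profile,
    mapping_rate,
    mfa_cutoff,
    parse_taxonomy,
    relative_abundance,
)


@pytest.mark.parametrize(
    "mapped, total, ra",
    [(100_000, 10_000_000, 1.0), (0, 10_000_000, 0.0), (10_000_000, 10_000_000, 100.0)],
)
def test_relative_abundance(mapped, total, ra):
    assert relative_abundance(mapped, total) == ra


def test_relative_abundance_errors():
    with pytest.raises(ValidationError):
        relative_abundance(1, 0)
    with pytest.raises(ValidationError):
        relative_abundance(11, 10)


@pytest.mark.parametrize("n, cutoff", [(11, 6), (10, 6), (1, 1), (2, 2), (12, 7)])
def test_mfa_cutoff_is_strict_majority(n, cutoff):
    assert mfa_cutoff(n) == cutoff


def test_mfa_cutoff_rejects_empty():
    with pytest.raises(ValidationError):
        mfa_cutoff(0)


def _matrix(counts: dict, totals: dict) -> AbundanceMatrix:
    frame = pd.DataFrame(counts).T
    frame.columns = list(totals)
    return AbundanceMatrix(
        frame.astype(np.int64), pd.Series(totals, dtype=np.int64)
    )


def _eleven_sample_matrix():
    total = 1_000_000
    counts = {
        "core_mag": [500] * 11,                     # mean RA 0.05% in all samples
        "mfa_thin": [50] * 7 + [0] * 4,             # detected in 7, mean RA 0.0032%
        "lfa_rich": [100_000] * 5 + [0] * 6,        # rich but only 5 samples
        "absent": [0] * 11,
    }
    totals = {f"S{i}": total for i in range(11)}
    return _matrix(counts, totals)


class TestFrequencyAndCore:
    def test_categories_and_core(self):
        profile = build_profile(_eleven_sample_matrix())
        cat = profile.frame["frequency_category"]
        assert cat["core_mag"] == "MfA"
        assert cat["mfa_thin"] == "MfA"  # 7 of 11 detections
        assert cat["lfa_rich"] == "LfA"  # 5 of 11, however abundant
        assert cat["absent"] == "LfA"
        assert profile.frame.loc["absent", "detection_frequency"] == 0
        # core needs MfA AND mean RA above 0.01%
        assert profile.core_set() == {"core_mag"}

    def test_partition_and_core_subset(self, default_sim):
        profile = build_profile(default_sim.abundance)
        cats = set(profile.frame["frequency_category"])
        assert cats <= {"MfA", "LfA"}
        mfa = set(profile.frame.index[profile.frame["frequency_category"] == "MfA"])
        assert profile.core_set() <= mfa

    def test_column_permutation_invariance(self, default_sim):
        matrix = default_sim.abundance
        permuted = AbundanceMatrix(
            matrix.counts.iloc[:, ::-1], matrix.total_reads.iloc[::-1]
        )
        a = build_profile(matrix).frame["frequency_category"]
        b = build_profile(permuted).frame["frequency_category"]
        assert a.equals(b)

    def test_raising_detection_threshold_never_promotes(self, default_sim):
        lo = build_profile(default_sim.abundance, detection_threshold=0.0).frame
        hi = build_profile(default_sim.abundance, detection_threshold=0.01).frame
        promoted = (lo["frequency_category"] == "LfA") & (
            hi["frequency_category"] == "MfA"
        )
        assert not promoted.any()
        assert (hi["detection_frequency"] <= lo["detection_frequency"]).all()


class TestMappingRate:
    def test_fully_mapped_sample(self):
        m = _matrix({"M1": [100]}, {"S1": 100})
        per_sample, means = mapping_rate(m)
        assert per_sample["S1"] == 100.0 and means["all"] == 100.0

    def test_group_mean(self):
        m = _matrix({"M1": [20, 30]}, {"S1": 100, "S2": 100})
        _, means = mapping_rate(m, {"S1": "biofloc", "S2": "biofloc"})
        assert means["biofloc"] == 25.0

    def test_unknown_sample_in_grouping_rejected(self):
        m = _matrix({"M1": [20]}, {"S1": 100})
        with pytest.raises(ValidationError):
            mapping_rate(m, {"S9": "biofloc"})

    def test_recovers_designed_mapped_fractions(self, default_sim):
        """The generator records its designed per-sample mapped fraction;
        multinomial sampling at 10M reads recovers it to within 0.1 point."""
        per_sample, _ = mapping_rate(default_sim.abundance)
        for s, frac in default_sim.ground_truth.mapped_fraction.items():
            assert per_sample[s] == pytest.approx(100 * frac, abs=0.1)

    def test_ra_sums_to_mapping_rate(self, default_sim):
        ra = default_sim.abundance.relative_abundance()
        per_sample, _ = mapping_rate(default_sim.abundance)
        assert np.allclose(ra.sum(axis=0), per_sample)
        assert (per_sample <= 100.0).all()


class TestAggregateByTaxon:
    def test_counts_partition_with_sentinel(self):
        profile = build_profile(_eleven_sample_matrix())
        taxes = {
            "core_mag": parse_taxonomy("d__Bacteria;p__P;c__C;o__O;f__FamA;g__;s__"),
            "mfa_thin": parse_taxonomy("d__Bacteria;p__P;c__C;o__O;f__FamA;g__;s__"),
            "lfa_rich": parse_taxonomy("d__Bacteria;p__P;c__C;o__O;f__;g__;s__"),
            "absent": parse_taxonomy("d__Bacteria;p__P;c__C;o__O;f__FamB;g__;s__"),
        }
        out = aggregate_by_taxon(profile, taxes, "family")
        assert out["n_mags"].to_dict() == {"FamA": 2, "unclassified": 1, "FamB": 1}
        assert out["n_mags"].sum() == 4

    def test_conservation_at_every_rank(self, default_sim):
        profile = build_profile(default_sim.abundance)
        for rank in ("phylum", "family", "genus"):
            out = aggregate_by_taxon(profile, default_sim.taxonomies, rank)
            assert out["n_mags"].sum() == len(profile.mag_ids)

    def test_missing_taxonomy_rejected(self):
        profile = build_profile(_eleven_sample_matrix())
        with pytest.raises(ValidationError):
            aggregate_by_taxon(profile, {}, "family")
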