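"""Quality score, tier assignment, MIMAG flag, and unclassified-rank tallies."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flocprofiler import (
    GenomeRecord,
    ValidationError,
    classify_tier,
    count_unclassified,
    mimag_high_flag,
    parse_taxonomy,
    quality_score,
)
from flocprofiler.quality import TIER_FAIL, TIER_HIGH, TIER_MEDIUM, TierThresholds

completeness = st.floats(0, 100, allow_nan=False)
contamination = st.floats(0, 20, allow_nan=False)


@pytest.mark.parametrize(
    "c, x, expected",
    [(100, 0, 100.0), (90, 5, 65.0), (50, 10, 0.0)],
)
def test_quality_score_values(c, x, expected):
    assert quality_score(c, x) == expected


def test_quality_score_rejects_out_of_range():
    with pytest.raises(ValidationError):
        quality_score(101, 0)
    with pytest.raises(ValidationError):
        quality_score(50, -1)


@settings(derandomize=True, max_examples=200)
@given(completeness, contamination, st.floats(0, 20), st.floats(0, 10))
def test_quality_score_is_linear(c, x, a, b):
    if c + a <= 100:
        assert quality_score(c + a, x) == pytest.approx(quality_score(c, x) + a)
    assert quality_score(c, x + b) == pytest.approx(quality_score(c, x) - 5 * b)


@pytest.mark.parametrize(
    "c, x, tier",
    [
        (95, 2, TIER_HIGH),
        (90, 5, TIER_HIGH),  # inclusive high boundary
        (60, 8, TIER_MEDIUM),
        (50, 9.99, TIER_MEDIUM),
        (49.9, 1, TIER_FAIL),
        (60, 10, TIER_FAIL),  # strict medium contamination bound
        (95, 7, TIER_MEDIUM),  # high completeness, too contaminated for high tier
    ],
)
def test_tier_rules(c, x, tier):
    assert classify_tier(c, x) == tier


def test_medium_bound_configurable():
    inclusive = TierThresholds(medium_contamination_inclusive=True)
    assert classify_tier(60, 10, inclusive) == TIER_MEDIUM


@settings(derandomize=True, max_examples=300)
@given(completeness, contamination)
def test_tier_partition(c, x):
    assert classify_tier(c, x) in (TIER_HIGH, TIER_MEDIUM, TIER_FAIL)


@settings(derandomize=True, max_examples=200)
@given(completeness, contamination, st.floats(0, 10), st.floats(0, 10))
def test_tier_monotonicity(c, x, dc, dx):
    order = {TIER_FAIL: 0, TIER_MEDIUM: 1, TIER_HIGH: 2}
    if c + dc <= 100:
        assert order[classify_tier(c + dc, x)] >= order[classify_tier(c, x)]
    assert order[classify_tier(c, x + dx)] <= order[classify_tier(c, x)]


def _record(rrna, trna):
    return GenomeRecord(
        mag_id="M1", completeness=95, contamination=1, genome_size=3_000_000,
        n_contigs=100, gc=50, rrna_present=rrna, trna_count=trna,
    )


@pytest.mark.parametrize(
    "tier, rrna, trna, expected",
    [
        (TIER_HIGH, {"5S", "16S", "23S"}, 20, True),
        (TIER_HIGH, {"5S", "16S", "23S"}, 18, True),  # MIMAG minimum inclusive
        (TIER_HIGH, {"16S", "23S"}, 30, False),
        (TIER_MEDIUM, {"5S", "16S", "23S"}, 40, False),
        (TIER_HIGH, {"5S", "16S", "23S"}, 17, False),
    ],
)
def test_mimag_flag(tier, rrna, trna, expected):
    assert mimag_high_flag(_record(rrna, trna), tier) is expected


class TestCountUnclassified:
    TAXA = [
        parse_taxonomy("d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;"
                       "o__Rhodobacterales;f__Rhodobacteraceae;g__Marivita;s__Marivita sp1"),
        parse_taxonomy("d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;"
                       "o__Rhodobacterales;f__Rhodobacteraceae;g__;s__"),
        parse_taxonomy("d__Bacteria;p__Bacteroidota;c__;o__;f__;g__;s__"),
    ]

    def test_counts_per_rank(self):
        assert count_unclassified(self.TAXA, "genus") == 2
        assert count_unclassified(self.TAXA, "species") == 2
        assert count_unclassified(self.TAXA, "phylum") == 0

    def test_fully_classified_is_zero_everywhere(self):
        t = [self.TAXA[0]]
        assert all(count_unclassified(t, r) == 0 for r in
                   ("domain", "phylum", "class", "order", "family", "genus", "species"))

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError):
            count_unclassified(self.TAXA, "kingdom")

    def test_nondecreasing_down_ranks(self, default_sim):
        taxa = list(default_sim.taxonomies.values())
        counts = [count_unclassified(taxa, r) for r in
                  ("phylum", "class", "order", "family", "genus", "species")]
        assert counts == sorted(counts)
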