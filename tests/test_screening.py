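"""dsrAB orientation, HN-AD marker screening, and 16S novelty classes."""

import pytest

from flocprofiler import (
    SimilarityRecord,
    ValidationError,
    classify_16s_novelty,
    classify_dsrab,
    novelty_calls,
    screen_hnad,
)
from flocprofiler.screening import novelty_counts
from flocprofiler.simulate import HNAD_MARKER_LENGTHS


def _rec(query, label, identity, length=300, ref=None):
    return SimilarityRecord(query, ref or f"ref_{label}", label, identity, length)


class TestDsrab:
    def test_clear_margin(self):
        out = classify_dsrab([_rec("q1", "oxidative", 85.0), _rec("q1", "reductive", 60.0)])
        assert out == {"q1": "oxidative"}

    def test_within_margin_is_ambiguous(self):
        out = classify_dsrab(
            [_rec("q1", "oxidative", 70.0), _rec("q1", "reductive", 69.5)], margin=2.0
        )
        assert out == {"q1": "ambiguous"}

    def test_no_labelled_hits_is_ambiguous(self):
        out = classify_dsrab([_rec("q1", "something_else", 90.0)])
        assert out == {"q1": "ambiguous"}

    def test_single_label_wins_outright(self):
        out = classify_dsrab([_rec("q1", "reductive", 80.0)])
        assert out == {"q1": "reductive"}

    def test_planted_orientations_recovered(self, default_sim):
        """Queries generated from labelled references at a clear identity
        margin get their planted orientation back."""
        truth = default_sim.ground_truth.dsrab_orientation
        assert truth  # the default community plants some dsrAB genomes
        out = classify_dsrab(default_sim.dsrab_similarity)
        assert {q: out[q] for q in truth} == truth


class TestHnad:
    def _records(self, identities):
        return [
            _rec("M1", marker, identity, length=HNAD_MARKER_LENGTHS[marker])
            for marker, identity in identities.items()
        ]

    def test_all_markers_strong_is_positive(self):
        recs = self._records({"DnfA": 95, "DnfB": 95, "DnfC": 95, "POD": 95})
        out = screen_hnad(recs, HNAD_MARKER_LENGTHS)
        assert out["M1"].positive

    def test_all_markers_weak_is_negative(self):
        recs = self._records({"DnfA": 30, "DnfB": 30, "DnfC": 30, "POD": 30})
        out = screen_hnad(recs, HNAD_MARKER_LENGTHS)
        assert not out["M1"].positive
        # identities are reported so the decision is reproducible
        assert out["M1"].marker_identity["DnfA"] == 30

    def test_dnf_conjunction_fails_without_all_subunits(self):
        recs = self._records({"DnfA": 90, "DnfB": 20, "DnfC": 90, "POD": 20})
        assert not screen_hnad(recs, HNAD_MARKER_LENGTHS)["M1"].positive

    def test_pod_alone_suffices(self):
        recs = self._records({"DnfA": 20, "DnfB": 20, "DnfC": 20, "POD": 80})
        assert screen_hnad(recs, HNAD_MARKER_LENGTHS)["M1"].positive

    def test_short_alignment_fails_coverage(self):
        recs = [_rec("M1", "POD", 95.0, length=100)]  # 33% of the 300-aa marker
        assert not screen_hnad(recs, HNAD_MARKER_LENGTHS)["M1"].positive

    def test_simulated_community_screens_negative(self, default_sim):
        out = screen_hnad(default_sim.hnad_similarity, HNAD_MARKER_LENGTHS)
        assert out and not any(r.positive for r in out.values())


class TestNovelty:
    @pytest.mark.parametrize(
        "identity, call",
        [
            (93.0, "novel_genus"),
            (97.0, "novel_species"),
            (99.5, "known_species"),
            (94.5, "novel_species"),  # boundary: strict < for the genus band
            (98.7, "known_species"),  # boundary: strict < for the species band
            (94.49, "novel_genus"),
            (0.0, "novel_genus"),
            (100.0, "known_species"),
        ],
    )
    def test_threshold_partition(self, identity, call):
        assert classify_16s_novelty(identity) == call

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_16s_novelty(101.0)

    def test_planted_calls_recovered(self, default_sim):
        truth = default_sim.ground_truth.novelty_call
        calls = novelty_calls(default_sim.novelty_similarity)
        assert {m: c.call for m, c in calls.items()} == truth
        counts = novelty_counts(calls)
        assert sum(counts.values()) == len(truth)
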