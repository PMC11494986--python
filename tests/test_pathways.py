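"""Rule-engine semantics against a brute-force oracle, marker calls, and
the pathway-by-sample z-score matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flocprofiler import (
    ValidationError,
    builtin_pathway_definitions,
    denitrifier_mode,
    marker_call,
    pathway_abundance_matrix,
    pathway_completeness,
    sox_rdsr_cooccurrence,
)
from flocprofiler.pathways import apply_dsrab_orientation, get_definition


def oracle_completeness(genes, definition):
    """Independent evaluation of the step/alternative/complex semantics by
    explicit iteration and membership tests."""
    satisfied = 0
    for step in definition.steps:
        step_ok = False
        for alternative in step:
            if all(symbol in genes for symbol in alternative):
                step_ok = True
        if step_ok:
            satisfied += 1
    return satisfied / len(definition.steps)


SOX_GENES = {"soxX", "soxA", "soxY", "soxZ", "soxB", "soxC", "soxD"}


class TestCompleteness:
    def test_full_sox_cluster(self):
        call = pathway_completeness(SOX_GENES, get_definition("sox"))
        assert call.completeness_fraction == 1.0 and call.complete

    def test_empty_gene_set(self):
        call = pathway_completeness(set(), get_definition("denitrification"))
        assert call.completeness_fraction == 0.0 and not call.complete

    def test_half_complete_denitrification(self):
        call = pathway_completeness(
            {"narG", "narH", "narI", "nirS"}, get_definition("denitrification")
        )
        assert call.completeness_fraction == 0.5
        assert call.satisfied_steps == {0, 1}

    def test_either_nitrate_reductase_satisfies_first_step(self):
        d = get_definition("denitrification")
        for genes in ({"napA", "napB"}, {"narG", "narH", "narI"}):
            assert 0 in pathway_completeness(genes, d).satisfied_steps
        assert 0 not in pathway_completeness({"napA", "narG"}, d).satisfied_steps

    @settings(derandomize=True, max_examples=500)
    @given(st.data())
    def test_matches_bruteforce_oracle(self, data):
        defs = builtin_pathway_definitions()
        d = data.draw(st.sampled_from(defs))
        union = sorted(d.symbol_union())[:12]
        genes = data.draw(st.sets(st.sampled_from(union)) if union else st.just(set()))
        # salt with symbols foreign to the pathway
        genes |= data.draw(st.sets(st.sampled_from(["recA", "glnA", "soxB", "nirK"])))
        call = pathway_completeness(genes, d)
        assert call.completeness_fraction == oracle_completeness(genes, d)
        assert call.complete == (call.completeness_fraction == 1.0)

    @settings(derandomize=True, max_examples=300)
    @given(st.data())
    def test_adding_genes_never_decreases_completeness(self, data):
        defs = builtin_pathway_definitions()
        d = data.draw(st.sampled_from(defs))
        union = sorted(d.symbol_union())
        genes = data.draw(st.sets(st.sampled_from(union)))
        extra = data.draw(st.sampled_from(union))
        before = pathway_completeness(genes, d).completeness_fraction
        after = pathway_completeness(genes | {extra}, d).completeness_fraction
        assert after >= before


class TestBuiltinDefinitions:
    def test_denitrification_has_four_steps(self):
        assert get_definition("denitrification").n_steps == 4

    def test_gs_gogat_needs_all_three_genes(self):
        d = get_definition("gs_gogat")
        assert pathway_completeness({"glnA", "gltB", "gltD"}, d).complete
        assert not pathway_completeness({"glnA", "gltB"}, d).complete

    def test_sox_single_step_needs_seven_symbols(self):
        d = get_definition("sox")
        assert d.n_steps == 1
        assert len(d.symbol_union()) == 7
        assert not pathway_completeness(SOX_GENES - {"soxC"}, d).complete

    def test_all_definitions_validate(self):
        defs = builtin_pathway_definitions()
        assert len({d.pathway_id for d in defs}) == len(defs) == 11


class TestMarkers:
    @pytest.mark.parametrize(
        "genes, process, expected",
        [
            ({"nirK"}, "denitrification", True),
            ({"nirS"}, "denitrification", True),
            ({"nirB"}, "dnra", False),  # complex incomplete
            ({"nirB", "nirD"}, "dnra", True),
            ({"soxB"}, "sox_oxidation", True),
            (set(), "sox_oxidation", False),
        ],
    )
    def test_marker_rules(self, genes, process, expected):
        assert marker_call(genes, process) is expected

    def test_unknown_process_rejected(self):
        with pytest.raises(ValidationError):
            marker_call({"nirS"}, "sulfate_reduction_marker")

    def test_denitrification_marker_implies_nitrite_step(self):
        d = get_definition("denitrification")
        for genes in ({"nirS"}, {"nirK"}, {"nirS", "nirK"}):
            assert marker_call(genes, "denitrification")
            assert 1 in pathway_completeness(genes, d).satisfied_steps


class TestDenitrifierMode:
    @pytest.mark.parametrize(
        "genes, mode",
        [
            ({"napA", "napB"}, "aerobic_capable"),
            ({"narG", "narH", "narI"}, "anaerobic_only"),
            ({"napA", "narG"}, "none"),
            ({"napA", "napB", "narG", "narH", "narI"}, "aerobic_capable"),
        ],
    )
    def test_modes(self, genes, mode):
        assert denitrifier_mode(genes) == mode


class TestSoxRdsr:
    def _calls(self, genes, scope="M1"):
        defs = [get_definition("sox"), get_definition("rdsr")]
        return [pathway_completeness(genes, d, scope_id=scope) for d in defs]

    def test_oxidative_dsrab_included(self):
        calls = self._calls(SOX_GENES | {"dsrA", "dsrB"})
        assert sox_rdsr_cooccurrence(calls, {"M1": "oxidative"}) == {"M1"}

    def test_reductive_dsrab_excluded(self):
        calls = self._calls(SOX_GENES | {"dsrA", "dsrB"})
        assert sox_rdsr_cooccurrence(calls, {"M1": "reductive"}) == set()

    def test_no_sox_complete_is_empty(self):
        calls = self._calls({"dsrA", "dsrB"})
        assert sox_rdsr_cooccurrence(calls, {"M1": "oxidative"}) == set()

    def test_orientation_gating_of_calls(self):
        calls = self._calls(SOX_GENES | {"dsrA", "dsrB"})
        gated = apply_dsrab_orientation(calls, {"M1": "reductive"})
        rdsr = next(c for c in gated if c.pathway_id == "rdsr")
        assert not rdsr.complete and rdsr.completeness_fraction == 0.0


class TestZScoreMatrix:
    def _bulk(self, counts_per_sample):
        rows = []
        for sample, n in counts_per_sample.items():
            rows += [(sample, f"{sample}:g{i}", "soxB") for i in range(n)]
        return pd.DataFrame(rows, columns=["sample_id", "gene_id", "symbol"])

    def test_row_z_scores(self):
        z, flagged = pathway_abundance_matrix(
            self._bulk({"S1": 2, "S2": 4, "S3": 6}), [get_definition("sox")]
        )
        assert np.allclose(z.loc["sox"], [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert flagged == []

    def test_constant_row_flagged_zero(self):
        z, flagged = pathway_abundance_matrix(
            self._bulk({"S1": 3, "S2": 3, "S3": 3}), [get_definition("sox")]
        )
        assert (z.loc["sox"] == 0).all()
        assert flagged == ["sox"]

    def test_rows_have_mean_zero_sd_one(self, default_sim):
        z, flagged = pathway_abundance_matrix(
            default_sim.bulk_genes, builtin_pathway_definitions()
        )
        values = z.to_numpy()
        assert np.allclose(values.mean(axis=1), 0.0, atol=1e-12)
        nonconstant = [i for i, p in enumerate(z.index) if p not in flagged]
        assert np.allclose(values[nonconstant].std(axis=1), 1.0, atol=1e-12)

    def test_single_sample_refuses_zscore(self):
        raw, flagged = pathway_abundance_matrix(
            self._bulk({"S1": 5}), [get_definition("sox")]
        )
        assert flagged == ["zscore_refused"]
        assert raw.loc["sox", "S1"] == 5
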