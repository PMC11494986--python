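"""Generator contracts: determinism, dropout calibration, occupancy
monotonicity, and ground-truth consistency."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from flocprofiler import (
    ConfigError,
    SimulationConfig,
    recovery_report,
    simulate,
)
from flocprofiler.community import mfa_cutoff
from flocprofiler.simulate import sample_counts, write_outputs


class TestConfig:
    def test_unknown_pathway_rejected(self):
        with pytest.raises(Exception):
            SimulationConfig(seed=0, pathway_probabilities={"not_a_pathway": 0.5})

    def test_infeasible_reads_rejected(self):
        with pytest.raises(Exception):
            SimulationConfig(seed=0, total_reads=0)

    def test_unknown_keys_rejected(self):
        with pytest.raises(Exception):
            SimulationConfig(seed=0, not_a_knob=1)


class TestDeterminism:
    def test_same_seed_is_byte_identical(self, tmp_path):
        config = SimulationConfig(seed=42, n_mags=40, n_taxa=15)
        a, b = tmp_path / "a", tmp_path / "b"
        paths_a = write_outputs(simulate(config), a)
        paths_b = write_outputs(simulate(config), b)
        for key in paths_a:
            assert filecmp.cmp(paths_a[key], paths_b[key], shallow=False), key

    def test_different_seeds_differ(self):
        a = simulate(SimulationConfig(seed=1, n_mags=30))
        b = simulate(SimulationConfig(seed=2, n_mags=30))
        assert not a.abundance.counts.equals(b.abundance.counts)


class TestEmittedTables:
    def test_column_sums_within_totals(self, default_sim):
        sums = default_sim.abundance.counts.sum(axis=0)
        assert (sums <= default_sim.abundance.total_reads).all()

    def test_truth_consistent_with_tables(self, default_sim):
        truth = default_sim.ground_truth
        assert set(truth.mag_taxon) == set(default_sim.abundance.mag_ids)
        assert set(truth.mag_taxon) == {r.mag_id for r in default_sim.genome_records}
        # a read count can only appear where the genome is truly present
        present = truth.presence
        counts = default_sim.abundance.counts
        assert not ((counts > 0) & ~present).any().any()

    def test_foreign_genes_absent_without_contamination(self, noiseless_sim):
        truth = noiseless_sim.ground_truth
        table = noiseless_sim.gene_table
        for mag, endowed in truth.endowed_symbols.items():
            assert table.symbols_for(mag) <= endowed | {"cazyme"}


class TestDropoutCalibration:
    def test_gene_presence_rate_matches_completeness(self):
        """With C = 80 each endowed gene is kept with probability 0.8;
        the empirical rate over 2,000 genomes stays within 3 binomial SEs."""
        config = SimulationConfig(
            seed=5, n_mags=2000, n_taxa=30, completeness_range=(80.0, 80.0),
            contamination_scale=0.0, foreign_genes_per_contamination_pct=0.0,
            mean_cazy_genes=0.0, emit_bulk=False,
        )
        res = simulate(config)
        truth = res.ground_truth
        emitted = len(res.gene_table)
        endowed = sum(len(s) for s in truth.endowed_symbols.values())
        p = 0.8
        se = np.sqrt(p * (1 - p) / endowed)
        assert abs(emitted / endowed - p) < 3 * se

    def test_no_dropout_at_full_completeness(self, noiseless_sim):
        truth = noiseless_sim.ground_truth
        table = noiseless_sim.gene_table
        for mag, endowed in truth.endowed_symbols.items():
            assert endowed <= table.symbols_for(mag)


class TestOccupancyMonotonicity:
    def test_higher_occupancy_never_loses_mfa(self):
        """Coupled on shared uniforms, raising the occupancy probability can
        only add presence, hence never demote a genome from MfA."""
        rng = np.random.default_rng(3)
        mags = [f"M{i}" for i in range(50)]
        samples = [f"S{j}" for j in range(11)]
        u = rng.random((50, 11))
        weights = pd.Series(rng.lognormal(0, 2, 50), index=mags)
        cutoff = mfa_cutoff(11)
        mfa = {}
        for p in (0.3, 0.7):
            presence = pd.DataFrame(u < p, index=mags, columns=samples)
            counts = sample_counts(
                np.random.default_rng(9), presence, weights, 10_000_000, 0.4
            )
            detected = (counts > 0).sum(axis=1)
            mfa[p] = set(detected.index[detected >= cutoff])
        assert mfa[0.3] <= mfa[0.7]


class TestRecoveryReport:
    def test_noiseless_recovery_is_perfect(self, noiseless_sim):
        from flocprofiler import RunConfig, run_all

        res = noiseless_sim
        pipeline = run_all(
            RunConfig(), genome_records=res.genome_records, gene_table=res.gene_table,
            abundance=res.abundance, taxonomies=res.taxonomies,
            dsrab_similarity=res.dsrab_similarity, write=False,
        )
        report = recovery_report(res.ground_truth, pipeline)
        assert (report["precision"] == 1.0).all()
        assert (report["recall"] == 1.0).all()

    def test_dropout_counts_false_negatives(self):
        from flocprofiler import RunConfig, run_all

        config = SimulationConfig(
            seed=13, n_mags=200, n_taxa=20, completeness_range=(60.0, 60.0),
            contamination_scale=0.0, foreign_genes_per_contamination_pct=0.0,
            emit_bulk=False,
        )
        res = simulate(config)
        pipeline = run_all(
            RunConfig(), genome_records=res.genome_records, gene_table=res.gene_table,
            abundance=res.abundance, taxonomies=res.taxonomies,
            dsrab_similarity=res.dsrab_similarity, write=False,
        )
        report = recovery_report(res.ground_truth, pipeline)
        assert report.loc["pathways", "fn"] > 0  # dropped-out pathways, not errors
        assert report.loc["pathways", "fp"] == 0  # no contamination, no spurious calls

    def test_id_mismatch_rejected(self, noiseless_sim, default_pipeline):
        with pytest.raises(ConfigError):
            recovery_report(noiseless_sim.ground_truth, default_pipeline)
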