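import pytest

from flocprofiler import RunConfig, SimulationConfig, run_all, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One study-condition simulation shared by read-only tests."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    res = default_sim
    return run_all(
        RunConfig(seed=11),
        genome_records=res.genome_records,
        gene_table=res.gene_table,
        abundance=res.abundance,
        taxonomies=res.taxonomies,
        bulk_genes=res.bulk_genes,
        dsrab_similarity=res.dsrab_similarity,
        hnad_similarity=res.hnad_similarity,
        novelty_similarity=res.novelty_similarity,
        write=False,
    )


@pytest.fixture
def noiseless_sim():
    """Complete genomes, no contamination: every endowed gene is emitted."""
    config = SimulationConfig(
        seed=7,
        n_taxa=25,
        n_mags=60,
        completeness_range=(100.0, 100.0),
        contamination_scale=0.0,
        foreign_genes_per_contamination_pct=0.0,
    )
    return simulate(config)
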