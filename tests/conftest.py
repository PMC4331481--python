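import pytest

from tdmrlink import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimConfig:
    """A small but structured study: enough genes/DMRs for every stage."""
    return sim.SimConfig(n_genes=250, n_dmrs=320, seed=11, rep_noise_sd=0.15)


@pytest.fixture(scope="session")
def small_study(small_config):
    """Genome, genes, DMRs, expression and truth for the small study."""
    genome, genes = sim.generate_genome_and_genes(small_config)
    dmrs, exprs, truth = sim.generate_methylation_expression(small_config, genes)
    return {
        "config": small_config,
        "genome": genome,
        "genes": genes,
        "dmrs": dmrs,
        "exprs": exprs,
        "truth": truth,
        "span": len(genome[small_config.chrom]),
    }
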