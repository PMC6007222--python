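import pytest
from hypothesis import settings

from syntelink.synthetic import SimulationParams, generate_genome_pair

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

SMALL_PARAMS = SimulationParams(
    n_chromosomes=2,
    genes_per_chromosome=30,
    gene_length_bp=300,
    intergenic_bp=200,
    divergence=0.02,
    inversion_count=1,
    inversion_length_genes=5,
    translocation_count=1,
    translocation_length_genes=4,
    seed=20,
)


@pytest.fixture(scope="session")
def small_pair():
    """A compact simulated genome pair: 2 chromosomes x 30 genes of 300 bp,
    2% divergence, one 5-gene inversion, one 4-gene translocation."""
    return generate_genome_pair(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_pipeline(small_pair):
    from syntelink.pipeline import run_pipeline

    return run_pipeline(
        small_pair.genes_a,
        small_pair.genes_b,
        small_pair.catalog_a,
        small_pair.catalog_b,
    )
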