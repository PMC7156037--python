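import pytest

from bsakit import GenomeConfig, GenomeModel, simulate_genome


@pytest.fixture(scope="session")
def genome5x30():
    """Five 30-Mb chromosomes, centred 30% pericentromeres, 4 cM/Mb."""
    genome, _ = simulate_genome(GenomeConfig(n_genes=10, n_tes=10))
    return genome


@pytest.fixture(scope="session")
def small_genome():
    """One 1.5-Mb chromosome, handy for window arithmetic by hand."""
    return GenomeModel(chromosomes=(("Chr1", 1_500_000),))


@pytest.fixture(scope="session")
def annotated_genome():
    """Genome plus a gene/TE annotation with 4x TE density in the
    pericentromeres — shared by the enrichment tests."""
    return simulate_genome(GenomeConfig(n_genes=2000, n_tes=2000, seed=11))
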