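import pytest

from ampliscreen.gene_model import build_gene_model
from ampliscreen.hiplex_sim import default_gene_model, default_sites


@pytest.fixture
def two_exon_model():
    """Minimal intron-bearing model: CDS ATG+TAA, intron at 4..9."""
    return build_gene_model("g2", "ATGGTACAGTAA", [(1, 3), (10, 12)])


@pytest.fixture(scope="session")
def synth_model():
    """The package's default synthetic gene (deterministic)."""
    return default_gene_model()


@pytest.fixture(scope="session")
def small_model():
    """A compact synthetic gene for fast cohort simulations."""
    return default_gene_model(n_codons=160, n_exons=2, intron_len=100)


@pytest.fixture(scope="session")
def small_sites(small_model):
    return default_sites(small_model)
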