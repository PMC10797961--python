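import pytest
from hypothesis import HealthCheck, settings

from toxannot.pipeline import Config, annotate_genome
from toxannot.simulate import make_fixture

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_fixture():
    """200-kb genome with 6 implanted genes (one pseudogene)."""
    genome, truth = make_fixture(seed=1, genome_length=200_000, n_contigs=2,
                                 n_genes=6, n_pseudogenes=1)
    return genome, truth


@pytest.fixture(scope="session")
def small_run(small_fixture):
    genome, truth = small_fixture
    return genome, truth, annotate_genome(genome, truth.database(), Config())


@pytest.fixture(scope="session")
def default_run():
    """The default study fixture: 1-Mb genome, 20 genes, one pseudogene."""
    genome, truth = make_fixture(seed=1, n_pseudogenes=1)
    return genome, truth, annotate_genome(genome, truth.database(), Config())
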