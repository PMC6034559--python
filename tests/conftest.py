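import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from raretaxa.simulate import SimulationConfig, generate_pangenome, generate_proteomes

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """The 10-gene / 4-conserved / 1-shared pan-genome, mutation-free."""
    return SimulationConfig(
        seed=1, n_inclusion_genomes=3, n_exclusion_genomes=2,
        n_reference_genes=10, n_conserved=4, n_exclusion_shared=1,
        gene_length_bp=300, point_mutation_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_pangenome(small_config):
    return generate_pangenome(small_config)


@pytest.fixture(scope="session")
def default_proteomes():
    return generate_proteomes(SimulationConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def random_protein(rng, length):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, len(aa), length))
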