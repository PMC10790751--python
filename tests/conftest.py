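import numpy as np
import pytest

from anigap.simulate import SimConfig, simulate_species

# A small species keeps per-test cost low: 3 genomovars x 3 genomes at
# 30 kb still yields 36 pairs with the full two-band structure.
SMALL = dict(
    genome_length=30_000,
    n_genomovars=3,
    genomes_per_genomovar=3,
    n_core_genes=20,
    n_accessory_pool=8,
    island_size=2,
    gene_length=600,
)


@pytest.fixture(scope="session")
def small_species():
    return simulate_species(SimConfig(seed=7, **SMALL))


@pytest.fixture(scope="session")
def small_pairs(small_species):
    from anigap.ani import pair_table

    genomes, _ = small_species
    return pair_table(genomes)


@pytest.fixture(scope="session")
def default_species():
    """One species at the default (study-condition) configuration."""
    return simulate_species(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_pairs(default_species):
    from anigap.ani import pair_table

    genomes, _ = default_species
    return pair_table(genomes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)
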