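import numpy as np
import pytest

from recsel.founder_genomes import GenomeSpec, generate_founders
from recsel.trait_architecture import assign_qtl_effects, sample_site_roles


@pytest.fixture(scope="session")
def small_spec():
    """A desk-scale genome: 2 chromosomes x 60 sites."""
    return GenomeSpec(n_chromosomes=2, sites_per_chromosome=60,
                      qtl_per_chromosome=12, chip_sites_per_chromosome=12)


@pytest.fixture(scope="session")
def small_founders(small_spec):
    return generate_founders(small_spec, 40, seed=11)


@pytest.fixture(scope="session")
def full_spec():
    """The study genome: 10 chromosomes x 1000 sites, 100 QTL + 50 chip."""
    return GenomeSpec()


@pytest.fixture(scope="session")
def full_founders(full_spec):
    return generate_founders(full_spec, 100, seed=7)


@pytest.fixture(scope="session")
def full_trait(full_founders, full_spec):
    rng = np.random.default_rng(5)
    qtl_sites, _ = sample_site_roles(full_spec, rng)
    return assign_qtl_effects(full_founders, qtl_sites, 1.0, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
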