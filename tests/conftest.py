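import numpy as np
import pytest

from haplodyn.config import SimulationConfig
from haplodyn import synthetic_data as sd


@pytest.fixture(scope="session")
def small_genome():
    """One 500 kb contig: 40 planted elements (half solo), 5 indels of 5-30 kb."""
    cfg = SimulationConfig(seed=5, n_contigs=1, contig_length=500_000,
                           n_intact_ltr=40, solo_fraction=0.5,
                           n_planted_indels=5,
                           indel_size_range=(5_000, 30_000)).validate()
    return sd.simulate_genome(cfg, methylome=False, expression=True)


@pytest.fixture(scope="session")
def meth_genome():
    """A 400 kb contig with methylome: genes + 20 elements, 10x, 3 replicates."""
    cfg = SimulationConfig(seed=11, n_contigs=1, contig_length=400_000,
                           n_intact_ltr=20, solo_fraction=0.3,
                           n_planted_indels=0).validate()
    return sd.simulate_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_seq(rng, n):
    return sd.random_dna(rng, n)
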