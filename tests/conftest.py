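import numpy as np
import pytest

from g4kit.simulate import SimConfig, make_genome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down simulation for fast unit tests."""
    return SimConfig(
        seed=11,
        chrom_sizes={"chr1": 30_000, "chr2": 30_000},
        spike_chrom_sizes={"dm_chr1": 5_000},
        n_sites_per_class=3,
        library_size=5_000,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return make_genome(small_config)
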