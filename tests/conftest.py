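import numpy as np
import pytest

from repairscape import SimConfig, build_toy_genome


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        genome_length=300_000,
        n_genes=50,
        n_reads=20_000,
        seed=101,
    )


@pytest.fixture(scope="session")
def toy(small_config):
    return build_toy_genome(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
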