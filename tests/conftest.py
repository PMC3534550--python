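import numpy as np
import pytest

from cnaseg import SimulationConfig, uniform_map


@pytest.fixture(scope="session")
def small_map():
    return uniform_map(n_chromosomes=3, probes_per_chromosome=100, chrom_length=5_000_000)


@pytest.fixture()
def base_cfg():
    return SimulationConfig(
        n_chromosomes=3, probes_per_chromosome=100, chrom_length=5_000_000, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
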