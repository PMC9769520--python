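import numpy as np
import pytest

import tnseqkit as tk


@pytest.fixture(scope="session")
def small_config() -> tk.SimulationConfig:
    """A desk-scale study: 60 kb genome, 60 genes, dense mutant pool."""
    return tk.SimulationConfig(
        genome_length=60_000,
        n_genes=42,
        n_insertions=2_500,
        read_length=60,
        library_size=6_000,
        per_base_error=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return tk.generate_genome(small_config)


@pytest.fixture(scope="session")
def small_pool(small_config, small_genome):
    genome, annotation = small_genome
    return tk.simulate_insertion_library(genome, annotation, small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
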