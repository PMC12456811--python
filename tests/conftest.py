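import numpy as np
import pytest

from ribodyn.synthetic_data import (
    SimulationConfig,
    simulate_footprints,
    simulate_transcriptome,
)
from ribodyn.transcriptome import Transcript


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_genes=60, depth=60_000)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    transcripts, truth = simulate_transcriptome(small_config)
    return transcripts, truth


@pytest.fixture(scope="session")
def small_footprints(small_config, small_dataset):
    transcripts, truth = small_dataset
    return simulate_footprints(transcripts, truth, small_config, "0h")


@pytest.fixture
def toy_transcript() -> Transcript:
    # 5'UTR AAA | CDS ATG GCC TAA | 3'UTR AA
    return Transcript("tx1", "g1", "AAAATGGCCTAAAA", 3, 12)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
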