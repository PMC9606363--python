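import numpy as np
import pytest

from sealmhc import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One fixed small simulated dataset shared across read-only tests."""
    cfg = SimulationConfig(
        seed=42,
        n_mothers_per_colony=8,
        clones_per_individual=(10, 16),
        artifact_rate=0.1,
        n_microsat_loci=12,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Artifact-free, bias-free dataset: clones match true alleles exactly."""
    cfg = SimulationConfig(
        seed=7,
        n_mothers_per_colony=8,
        clones_per_individual=(12, 18),
        artifact_rate=0.0,
        n_microsat_loci=10,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
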