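import numpy as np
import pytest

from confmvpa import SimulationConfig, simulate_subject


@pytest.fixture
def tiny_config():
    """Small but structurally complete design: 3 runs, 12 trials/condition."""
    return SimulationConfig(
        n_subjects=4, n_voxels=12, trials_per_condition=12, n_runs=3,
        noise_sd=1.0,
    )


@pytest.fixture
def null_subject(tiny_config):
    trials, D, truth = simulate_subject(tiny_config, subject_seed=42)
    return trials, D, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
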