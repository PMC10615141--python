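import numpy as np
import pytest

from ssvepdyn.synthetic import SimulationConfig, generate_dataset, weight_for_db


def fast_config(**overrides) -> SimulationConfig:
    """Small, quick simulation config for unit tests (250 Hz virtual channel)."""
    defaults = dict(sample_rate=250.0, n_participants=3, n_trials_per_condition=6,
                    seed=42)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def noise_free_config(**overrides) -> SimulationConfig:
    """Deterministic signal-only config (no noise, no artifacts)."""
    defaults = dict(sample_rate=250.0, n_participants=2, n_trials_per_condition=3,
                    noise_sd=0.0, artifact_rate=0.0, seed=7)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = fast_config()
    recordings, truth = generate_dataset(cfg)
    return cfg, recordings, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
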