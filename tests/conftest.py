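import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pattlearn import SimulationConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated study: 6 subjects, 2 ROIs, 12 days."""
    cfg = SimulationConfig(
        n_subjects=6,
        n_voxels=20,
        n_rois=2,
        coupled_rois=("left_pars_opercularis",),
        seed=42,
    )
    patterns, behavior, truth = simulate_dataset(cfg)
    return cfg, patterns, behavior, truth


@pytest.fixture(scope="session")
def default_dataset():
    """One study at the default full-size conditions (24 subjects, 4 ROIs)."""
    cfg = SimulationConfig(seed=7)
    patterns, behavior, truth = simulate_dataset(cfg)
    return cfg, patterns, behavior, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
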