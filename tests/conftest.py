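import numpy as np
import pandas as pd
import pytest

from lppkit.config import AnalysisConfig, GeneratorConfig
from lppkit.simulate import simulate_study


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """A small but structurally complete synthetic study configuration."""
    return GeneratorConfig(
        n_subjects=8,
        trials_per_cell=6,
        n_channels=16,
        roi_channels=(3, 5, 8, 12),
        sfreq=100.0,
        epoch=(-0.1, 1.0),
        trial_noise_sd=4.0,
        subject_sd=1.0,
        pink_noise_scale=1.5,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_ana(small_cfg) -> AnalysisConfig:
    return AnalysisConfig(roi_channels=small_cfg.roi_channels, n_perm=50, n_boot=1000, seq_orderings=10)


@pytest.fixture(scope="session")
def tiny_study(small_cfg):
    """(epochs, trials) of the small synthetic study; shared, treat as read-only."""
    return simulate_study(small_cfg)


def exact_moments(n: int, mean: float, sd: float, rng=None) -> np.ndarray:
    """A vector with exactly the requested sample mean and (ddof=1) SD."""
    rng = rng or np.random.default_rng(0)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


@pytest.fixture
def make_exact_vector():
    return exact_moments
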