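import numpy as np
import pytest

from fluctcomm import CommunityParams, NoiseParams


@pytest.fixture
def baseline_noise():
    """Default noise set: gamma=0.05, tau=10 (sigma_r=0.05)."""
    return NoiseParams(mean_fitness=1.0, gamma=0.05, tau=10.0)


@pytest.fixture
def small_community(baseline_noise):
    return CommunityParams(n_species=20, noise=baseline_noise)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def seff_reduce(n):
    """Per-run Simpson effective richness for ensemble reductions."""
    p = n / n.sum(axis=1, keepdims=True)
    return 1.0 / (p**2).sum(axis=1)
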