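import numpy as np
import pytest

from nbmix import SimScenario, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grouped_counts(seed, n=300, k=30, beta=0.4, theta=2.0, tau=0.7):
    """One clustered NB dataset with fixed truth (study-range defaults)."""
    sc = SimScenario(n=n, k_groups=k, beta_regime="high", rho_regime="weak",
                     seed=seed, beta=beta, theta=theta, tau=tau)
    return simulate_dataset(sc, seed=seed)


@pytest.fixture
def grouped_counts():
    return make_grouped_counts(seed=7)
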