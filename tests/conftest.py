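import numpy as np
import pandas as pd
import pytest

from stromamark.synthetic_data import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def small_cfg():
    """Down-scaled synthetic configuration for fast unit tests."""
    return SyntheticConfig(
        seed=7, n_proteins=300, planted_fibro_enriched=30, planted_epi_enriched=12,
        n_genes=60, planted_up_genes=6, planted_down_genes=3,
    )


def random_survival(rng, n, censor_frac=0.3, scale=10.0):
    """Small random right-censored cohort for oracle comparisons."""
    times = np.round(rng.exponential(scale, size=n), 1) + 0.1
    events = rng.random(n) > censor_frac
    if not events.any():
        events[0] = True
    return times, events


@pytest.fixture
def random_survival_factory(rng):
    def make(n=12, censor_frac=0.3):
        return random_survival(rng, n, censor_frac)

    return make
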