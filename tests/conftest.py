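from dataclasses import replace

import numpy as np
import pytest

from mpiaf import cohort as ch


@pytest.fixture(scope="session")
def base_profile() -> ch.ObserverProfile:
    """One fixed observer with typical traits."""
    return ch.make_cohort(ch.CohortSpec(n_observers=1, seed=9))[0]


@pytest.fixture(scope="session")
def clean_profile(base_profile) -> ch.ObserverProfile:
    """Observer with a strong, central alpha peak and no lapses."""
    return replace(
        base_profile,
        lapse_rate=0.0,
        alpha_cf=10.3,
        alpha_power=1.5,
        alpha_bw=0.8,
        aperiodic_offset=1.0,
        aperiodic_exponent=1.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
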