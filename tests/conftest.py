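import numpy as np
import pytest

from neurostab import SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with planted signal: 12 regions (66 edges), d = 2."""
    cfg = SynthConfig(n_low=20, n_high=24, n_regions=12, n_informative_edges=5,
                      effect_size=2.0, cognition_r2=0.5, seed=101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no group effect anywhere (effect_size = 0)."""
    cfg = SynthConfig(n_regions=12, n_informative_edges=5, effect_size=0.0,
                      cognition_r2=0.0, seed=202)
    return generate_cohort(cfg)
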