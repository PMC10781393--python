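import numpy as np
import pytest

from stridesense import SyntheticConfig, generate_cohort, null_config


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a clear fatigue effect (30% amplitude attenuation)."""
    cfg = SyntheticConfig(n_participants=5, strides_per_condition=20,
                          amplitude_attenuation=0.3, variance_inflation=0.5,
                          outlier_prob=0.05, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No-effect cohort: F and NF strides are exchangeable."""
    cfg = null_config(n_participants=5, strides_per_condition=20, seed=12)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
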