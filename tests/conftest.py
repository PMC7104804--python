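import numpy as np
import pytest

from braincam.model import BlockSpec, NetConfig, RegressionNet
from braincam.phantom import PhantomSpec, SignalSphere, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_config():
    """A 2-block toy network small enough for finite-difference checks."""
    return NetConfig(
        blocks=[BlockSpec(3, 1, 2, followed_by_pool=True), BlockSpec(3, 2, 4)],
        hidden_units=4,
        dropout_rate=0.0,
        use_covariates=True,
        n_covariates=2,
        input_shape=(8, 8, 8),
    )


@pytest.fixture
def toy_net(toy_config):
    return RegressionNet(toy_config, seed=7, dtype=np.float64)


def toy_phantom_spec(seed=0, **overrides):
    """A 16³ phantom small enough for fast protocol tests."""
    defaults = dict(
        volume_shape=(16, 16, 16),
        background_semiaxes=(7.0, 7.0, 7.0),
        signal_regions=[SignalSphere(center=(7, 7, 7), radius=3.0, coupling=1.0)],
        sex_region_index=0,
        noise_sd=1.0,
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture
def toy_cohort():
    """24 train / 8 validation 16³ phantom subjects."""
    spec = toy_phantom_spec(seed=3)
    table, truth = generate_cohort(spec, 32)
    from braincam.volume_io import CohortTable

    train = CohortTable(table.records[:24], "train")
    val = CohortTable(table.records[24:], "validation")
    return train, val, truth, spec
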