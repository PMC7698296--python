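import numpy as np
import pytest

from farmvisits.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study: 40 farms, 6 birds, 2
    semesters, reduced tracking effort.  Shared across tests."""
    cfg = SimConfig(
        seed=7,
        extent=(0, 0, 15_000, 12_000),
        n_farms=40,
        n_birds=6,
        n_semesters=2,
        tracked_day_fraction=0.6,
        movement_radius_m=6_000,
        hours_active=5.0,
        dropout_bird_fraction=0.2,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
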