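import numpy as np
import pytest

from dendromort import growth
from dendromort.synthetic_data import SimulationConfig, simulate_site


@pytest.fixture(scope="session")
def sp_site():
    """One default (SP-like) simulated site shared across tests."""
    return simulate_site(SimulationConfig(seed=123))


@pytest.fixture(scope="session")
def sp_bai(sp_site):
    return {s.tree_id: growth.to_bai(s) for s in sp_site.series}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def null_config(seed: int, **overrides) -> SimulationConfig:
    """A configuration with living and dead groups exchangeable."""
    kwargs = dict(
        seed=seed,
        height_mean_dead=14.1,
        height_sd_dead=4.4,
        dbh_mean_dead=32.6,
        dbh_sd_dead=4.4,
        height_dbh_corr_dead=0.65,
        decline_rate=1.0,
        release_rate=1.0,
        drought_beta_dead=0.20,
        death_year_probs={2014: 1.0},
        n_anatomy_couples=0,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
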