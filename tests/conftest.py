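import numpy as np
import pytest

from greensentry import synthdata
from greensentry.config import build_config


@pytest.fixture(scope="session")
def sim_config():
    return synthdata.SimConfig(n_events=6, days_per_event=10, images_per_day=3,
                               image_size=64, risk_lag_days=2.0, episode_prob=0.8,
                               seed=7)


@pytest.fixture(scope="session")
def dataset(sim_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("synth")
    return synthdata.generate_dataset(sim_config, str(out))


@pytest.fixture(scope="session")
def desk_app():
    """Desk-profile application config matched to the session dataset."""
    return build_config({"train": {"epochs": 2, "seed": 0}}, profile="desk")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
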