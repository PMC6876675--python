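import warnings

import numpy as np
import pytest

from ipwdid import default_config, default_food_group_map, generate_panel

# matching warnings about dropped treated households are expected in small samples
warnings.filterwarnings("ignore", message=".*dropped.*treated household.*")


@pytest.fixture(scope="session")
def fg_map():
    return default_food_group_map()


@pytest.fixture(scope="session")
def small_config():
    return default_config(seed=7, n_households=160)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_panel(small_config)


@pytest.fixture(scope="session")
def default_panel():
    return generate_panel(default_config(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
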