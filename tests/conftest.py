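import numpy as np
import pytest

from dcbnet.synthetic_data import default_config, generate_panel


#: representative parameter settings per family, used across test modules
FAMILY_SETTINGS = {
    "gaussian": [(-0.6,), (0.3,), (0.8,)],
    "clayton": [(0.5,), (2.0,), (6.0,)],
    "frank": [(-5.0,), (2.0,), (8.0,)],
    "gumbel": [(1.2,), (2.0,), (4.0,)],
    "joe": [(1.2,), (2.0,), (4.0,)],
    "amh": [(-0.7,), (0.4,), (0.9,)],
    "raftery": [(0.2,), (0.5,), (0.8,)],
    "marshall_olkin": [(0.3, 0.8), (0.5, 0.5), (0.9, 0.4)],
    "roch_alegre": [(0.5, 1.5), (1.5, 2.0), (2.5, 1.0)],
}


@pytest.fixture(scope="session")
def study_panel():
    """One study-like synthetic panel shared across test modules."""
    return generate_panel(default_config(n_units=1500, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
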