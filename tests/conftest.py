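import numpy as np
import pytest

import stagescreen as ss
from stagescreen.data import STAGES


SHORT_LENGTHS = {s: (5, 9) for s in STAGES}


def make_sessions(n_per_class=2, seed=0, length_range=None):
    params = ss.default_params(
        class_counts=(n_per_class,) * 3,
        length_range=length_range or SHORT_LENGTHS,
        seed=seed,
    )
    return ss.simulate_dataset(params)


@pytest.fixture(scope="session")
def tiny_sessions():
    """Six short subjects, two per class."""
    return make_sessions(n_per_class=2, seed=0)


@pytest.fixture()
def tiny_config():
    """A configuration small enough for sub-second training."""
    return ss.ModelConfig(
        hidden_size=3,
        num_recurrent_layers=1,
        head_hidden=5,
        epochs=2,
        batch_size=3,
        seed=0,
    )
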