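import numpy as np
import pytest

from doafuse.preprocess import Epoch
from doafuse.synthetic import StateSpec, default_state_specs, generate_state_eeg


@pytest.fixture(scope="session")
def specs():
    return default_state_specs()


@pytest.fixture(scope="session")
def awake_epoch(specs):
    return Epoch(generate_state_eeg(specs["awake"], 60, 100, seed=101).samples, 0)


@pytest.fixture(scope="session")
def deep_epoch(specs):
    return Epoch(generate_state_eeg(specs["deep"], 60, 100, seed=101).samples, 0)


@pytest.fixture(scope="session")
def beta_only_spec():
    return StateSpec(state="awake", band_weights={"beta": 1.0}, ref_index_range=(84.0, 97.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
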