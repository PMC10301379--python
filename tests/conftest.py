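import numpy as np
import pytest
from hypothesis import settings

from symaxion.features import EpochSet
from symaxion.montage import build_default_layout
from symaxion.synthetic import SynthConfig, generate

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return build_default_layout()


@pytest.fixture(scope="session")
def small_epochs(layout):
    """A small, easily separable synthetic set shared across tests."""
    return generate(SynthConfig(n_epochs_per_class=6, seed=7), layout)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def white_noise_epochs(layout, rng):
    """White-noise epochs with identical per-channel variance, labelled 0."""
    data = rng.standard_normal((16, layout.n_channels, 200))
    return EpochSet(data, 200.0, np.zeros(16, dtype=int), ("only",))
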