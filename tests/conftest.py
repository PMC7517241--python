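import numpy as np
import pytest

from vqent.embedding_entropy import EntropyParams
from vqent.preprocess import FilterSpec, bandpass
from vqent.synthdata import SynthSpec, generate, montage_for


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """A compact two-class set: 12 trials/class, 4 channels."""
    return SynthSpec(n_trials_per_class=12, n_channels=4, seed=42)


@pytest.fixture(scope="session")
def small_trials(small_spec):
    return generate(small_spec)


@pytest.fixture(scope="session")
def small_trials_bp(small_trials):
    return bandpass(small_trials, FilterSpec())


@pytest.fixture(scope="session")
def small_montage(small_spec):
    return montage_for(small_spec)


@pytest.fixture
def default_params():
    return EntropyParams(M=2, rho=0.3, estimator="sampen")
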