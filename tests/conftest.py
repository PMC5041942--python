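import numpy as np
import pytest
from hypothesis import settings

from mircross.config import SyntheticConfig, null_config
from mircross import synthdata

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """One realization of the default planted study conditions."""
    return synthdata.generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def null_dataset():
    """A realization with no planted structure at all."""
    return synthdata.generate_dataset(null_config(seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
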