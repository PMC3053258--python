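import numpy as np
import pytest

from plantpin import ParameterSet
from plantpin.synthetic import SyntheticSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def monocot():
    return ParameterSet()


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study conditions: 5 planted hairpins + 1 decoy in a CDS."""
    return make_dataset(SyntheticSpec(seed=3))


@pytest.fixture(scope="session")
def mature_library(dataset):
    return [m.sequence for m in dataset.matures]
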