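import numpy as np
import pytest

from plidrift.montage import MontageSpec, make_default_montage


@pytest.fixture(scope="session")
def default_montage():
    return make_default_montage()


@pytest.fixture()
def small_montage():
    """A 4-channel montage for cheap network-level tests."""
    return MontageSpec(labels=("C3", "Cz", "C4", "P3"), reference_labels=("M1", "M2"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
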