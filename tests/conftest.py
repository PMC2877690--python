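import warnings

import numpy as np
import pytest

from twilightfold import load_energy_matrix, load_scale


@pytest.fixture(autouse=True)
def _quiet_short_sequence_warnings():
    # many fixtures use deliberately short sequences; the length warning is
    # tested explicitly where it matters
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*residues; index calls below.*"
        )
        yield


@pytest.fixture(scope="session")
def packing_scale():
    return load_scale("packing")


@pytest.fixture(scope="session")
def flexibility_scale():
    return load_scale("flexibility")


@pytest.fixture(scope="session")
def energy_matrix():
    return load_energy_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
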