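import numpy as np
import pytest

from sfdikit import build_lut, make_basis


@pytest.fixture(scope="session")
def lut():
    """Default reflectance table at the working [0, 0.2] mm^-1 pair."""
    return build_lut()


@pytest.fixture(scope="session")
def basis900():
    """Water/lipid Beer's-law basis on the 900-1000 nm, 5-nm grid."""
    return make_basis(["water", "lipid"], np.arange(900.0, 1001.0, 5.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
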