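import pytest

from tmdslip import PairingEnergyModel, enumerate_slippery_heptamers
from tmdslip.tmd import DgScale


@pytest.fixture(scope="session")
def model():
    return PairingEnergyModel()


@pytest.fixture(scope="session")
def census(model):
    """Full 16,384-heptamer census with the bundled calibrated model."""
    return enumerate_slippery_heptamers(model)


@pytest.fixture(scope="session")
def scale():
    return DgScale.default()
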