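import pytest

from feedopt import ModelCoefficients
from feedopt.io import load_packaged_scenario


@pytest.fixture(scope="session")
def coeffs():
    return ModelCoefficients.default()


@pytest.fixture(scope="session")
def scenarios():
    """The four packaged seasonal scenario configs, by lowercase season."""
    return {
        name: load_packaged_scenario(name)
        for name in ("spring", "summer", "autumn", "winter")
    }


@pytest.fixture()
def spring(scenarios):
    return scenarios["spring"]
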