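import numpy as np
import pytest

from borondose.synthetic import (
    GeneratorConfig,
    load_preset,
    lq_from_preset,
    mixed_field_from_preset,
)


@pytest.fixture(scope="session")
def invitro_preset():
    return load_preset("invitro")


@pytest.fixture(scope="session")
def survival_preset():
    return load_preset("survival")


@pytest.fixture(scope="session")
def biodist_preset():
    return load_preset("biodistribution")


@pytest.fixture(scope="session")
def mixed_field(invitro_preset):
    return mixed_field_from_preset(invitro_preset)


@pytest.fixture(scope="session")
def photon_lq(invitro_preset):
    return lq_from_preset(invitro_preset)


@pytest.fixture()
def config():
    return GeneratorConfig(seed=123)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
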