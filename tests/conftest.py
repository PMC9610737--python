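import pytest

from svirdelay import HistorySpec, load_preset


@pytest.fixture(scope="session")
def extinction_preset():
    return load_preset("extinction")


@pytest.fixture(scope="session")
def persistence_preset():
    return load_preset("persistence")


@pytest.fixture(scope="session")
def base_params(extinction_preset):
    """Base parameter set with beta1=10.5, beta2=5.5."""
    return extinction_preset.params


@pytest.fixture(scope="session")
def persistence_params(persistence_preset):
    """Base parameter set with beta1=14, beta2=7."""
    return persistence_preset.params


@pytest.fixture(scope="session")
def standard_history():
    return HistorySpec.constant(0.3, 0.3, 0.2)
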