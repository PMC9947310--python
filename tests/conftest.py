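import pytest

from sydicos import make_scenario, make_synthetic_diets, make_toy_hepatic_model


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_hepatic_model()


@pytest.fixture(scope="session")
def diets():
    return make_synthetic_diets()  # (cd, wd)


@pytest.fixture(scope="session")
def scenario():
    return make_scenario(seed=1)
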