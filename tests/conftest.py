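import pytest

from homeostat import presets


@pytest.fixture(scope="session")
def mono():
    return presets.monophasic()


@pytest.fixture(scope="session")
def biphasic():
    return presets.biphasic()


@pytest.fixture(scope="session")
def biphasic_narrow():
    return presets.biphasic_narrow()
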