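import pytest

from teecea.lifetable_synth import default_fixture
from teecea.params import default_config_path, load_config


@pytest.fixture(scope="session")
def bundle():
    """(ParameterSet, subgroups, synthetic LifeTable) at the bundled defaults."""
    return default_fixture()


@pytest.fixture(scope="session")
def params(bundle):
    return bundle[0]


@pytest.fixture(scope="session")
def subgroups(bundle):
    return bundle[1]


@pytest.fixture(scope="session")
def lifetable(bundle):
    return bundle[2]


@pytest.fixture(scope="session")
def config():
    return load_config(default_config_path())


@pytest.fixture(scope="session")
def arteriopathy_or(config):
    return config.euroscore.arteriopathy_or
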