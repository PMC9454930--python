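import pytest
from hypothesis import settings

from lcscreen import LifeTable, default_parameters, default_subgroups

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life():
    return LifeTable.bundled()


@pytest.fixture(scope="session")
def subgroups():
    return default_subgroups()
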