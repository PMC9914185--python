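import pytest

from poriaopt import default_groups, poria_dataset


@pytest.fixture(scope="session")
def poria():
    return poria_dataset()


@pytest.fixture(scope="session")
def groups():
    return default_groups()


@pytest.fixture(scope="session")
def group1(groups):
    return groups[0]


@pytest.fixture(scope="session")
def group2(groups):
    return groups[1]
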