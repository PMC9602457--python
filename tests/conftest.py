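import pytest

from greycast import TrainTestSplit, builtin_fixture


@pytest.fixture(scope="session")
def split():
    return TrainTestSplit(8, 2)


@pytest.fixture(scope="session")
def birth_rate():
    return builtin_fixture("china_birth_rate")


@pytest.fixture(scope="session")
def jiangsu():
    return builtin_fixture("jiangsu_registered")


@pytest.fixture(scope="session")
def nanjing():
    return builtin_fixture("nanjing_male")
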