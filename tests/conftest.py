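import pytest

from dcjtriad.fixtures import figure1, figure3, figure4


@pytest.fixture(scope="session")
def fig1():
    return figure1()


@pytest.fixture(scope="session")
def fig3():
    return figure3()


@pytest.fixture(scope="session")
def fig4():
    return figure4()
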