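import pytest

from riskcoev import GameParams, get_preset


@pytest.fixture(scope="session")
def game():
    """Reference game: N=6, M=3, b=1, c=0.1."""
    return GameParams(N=6, M=3, b=1.0, c=0.1)


@pytest.fixture(scope="session")
def system_I_bistable():
    return get_preset("fig4-top")


@pytest.fixture(scope="session")
def system_I_hopf():
    return get_preset("fig4-hopf")


@pytest.fixture(scope="session")
def system_II_bistable():
    return get_preset("fig6-top")


@pytest.fixture(scope="session")
def system_II_hopf():
    return get_preset("fig6-hopf")
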