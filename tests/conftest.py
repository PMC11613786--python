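import pytest

from cgrkit.io import load_case, load_case_data
from cgrkit.simulate import simulate_scenario


@pytest.fixture(scope="session")
def case_data():
    return load_case_data()


@pytest.fixture(scope="session")
def chr21_length(case_data):
    return case_data["reference"]["length"]


@pytest.fixture(scope="session")
def rd_p505():
    return load_case("RD_P505")


@pytest.fixture(scope="session")
def rd_p26():
    return load_case("RD_P26")


@pytest.fixture(scope="session")
def rd_p01():
    return load_case("RD_P01")


@pytest.fixture(scope="session")
def scenarios():
    """The three packaged scenarios, simulated once (derivative truth only)."""
    return {
        name: simulate_scenario(name, seed=1, trio=False, depth=False)
        for name in ("chromoanasynthesis_dup6", "ring21", "mixed_delsdups13")
    }
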