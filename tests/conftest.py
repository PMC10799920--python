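import pytest

import tmesense as tm


@pytest.fixture(scope="session")
def params():
    return tm.default_params()


@pytest.fixture(scope="session")
def lldr_direct():
    return tm.default_strain("pLldR", "DIRECT")


@pytest.fixture(scope="session")
def lldr_switch():
    return tm.default_strain("pLldR", "SWITCH")


@pytest.fixture(scope="session")
def lldr_lysis():
    return tm.default_strain("pLldR", "SWITCH_LYSIS")


@pytest.fixture(scope="session")
def saturating_lactate():
    return tm.EnvironmentSignal(lactate=10.0)
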