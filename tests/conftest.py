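import pytest

from qsarfusion import load_fixture


@pytest.fixture(scope="session")
def table1():
    """25 training inhibitors + 3 training-stage prediction systems."""
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    """133 testing inhibitors + 6 prediction systems (BB…FC)."""
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    """21 post-docking screening candidates."""
    return load_fixture("table3")
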