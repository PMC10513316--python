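import pytest

from blockamp import (
    build_fixture_templates,
    default_panel,
    default_signature,
    fixture_locus,
    load_table1,
    load_table2,
    load_table3,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def templates():
    return build_fixture_templates()


@pytest.fixture(scope="session")
def detection_template(templates):
    return templates[0]


@pytest.fixture(scope="session")
def nanopore_template(templates):
    return templates[1]


@pytest.fixture(scope="session")
def locus():
    return fixture_locus()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def signature():
    return default_signature()


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def table3():
    return load_table3()
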