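import pytest

from telogain import builtin_table1


@pytest.fixture(scope="session")
def catalog():
    return builtin_table1()


@pytest.fixture(scope="session")
def catalog_by_id(catalog):
    return {rec.study_id: rec for rec in catalog}
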