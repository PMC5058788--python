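import pytest

from mcrc_cea import paper_fixture


@pytest.fixture(scope="session")
def analysis1():
    return paper_fixture(1)


@pytest.fixture(scope="session")
def analysis2():
    return paper_fixture(2)
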