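import pytest

from mesothresh import builtin_table1


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()
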