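import pytest

from bovmt.haplogroups import default_definitions
from bovmt.simulate import synthetic_reference


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference()


@pytest.fixture(scope="session")
def definitions():
    return default_definitions()
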