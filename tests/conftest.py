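import pytest

from defencesim.params import SimParams


@pytest.fixture(scope="session")
def params() -> SimParams:
    """Default study parameters shared across tests."""
    return SimParams()
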