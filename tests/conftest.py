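import hypothesis
import pytest

import spatialflux as sf

hypothesis.settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def pdu():
    return sf.preset("pdu")


@pytest.fixture(scope="session")
def mev():
    return sf.preset("mevalonate")
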