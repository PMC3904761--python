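import hypothesis
import pytest

from opbnet import fixtures

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def rc_network():
    return fixtures.rc_circuit()


@pytest.fixture
def windkessel_network():
    return fixtures.windkessel()


@pytest.fixture
def lc_network():
    return fixtures.lc_oscillator()
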