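import pytest
from hypothesis import settings

from aqp_profiler.synthetic import make_reference_panel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    """Default synthetic reference panel (two anchors per subfamily)."""
    return make_reference_panel(0)
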