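import pytest

from ifpkit.chem_model import default_pattern_registry
from ifpkit.interactions import default_interaction_registry


@pytest.fixture(scope="session")
def registry():
    return default_interaction_registry()


@pytest.fixture()
def patterns():
    # fresh copy so tests may register/overwrite freely
    return default_pattern_registry()
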