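import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from livesysmap.synthetic import WorldSpec, simulate_world


@pytest.fixture(scope="session")
def chicken_world():
    """A 60-unit synthetic chicken world shared across tests."""
    spec = WorldSpec(n_units=60, seed=3)
    return spec, *simulate_world(spec, "chicken")


@pytest.fixture(scope="session")
def pig_world():
    spec = WorldSpec(n_units=60, seed=5)
    return spec, *simulate_world(spec, "pig")
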