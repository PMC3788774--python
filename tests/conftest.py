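import pytest

from mthet.genome_map import GenomeMap
from mthet.synthetic import simulate_reference


@pytest.fixture(scope="session")
def gmap() -> GenomeMap:
    return GenomeMap.default()


@pytest.fixture(scope="session")
def reference(gmap) -> str:
    """Synthetic rCRS-like reference with anchored study positions."""
    return simulate_reference(gmap, seed=7)
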