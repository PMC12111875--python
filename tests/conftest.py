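import pytest

from mitoprofile.reference import hitama_annotation
from mitoprofile.simulate import simulate_genome


@pytest.fixture(scope="session")
def hitama():
    """The published H. itama annotation (no sequence)."""
    return hitama_annotation()


@pytest.fixture(scope="session")
def sim0():
    """A default synthetic genome, seed 0 (shared, read-only)."""
    return simulate_genome(seed=0)
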