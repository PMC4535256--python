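import numpy as np
import pytest

from indelmark.simulate import simulate_reference


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome():
    """A 10-kb random single-chromosome reference."""
    return simulate_reference(10_000, seed=42)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
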