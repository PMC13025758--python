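import pytest

from snpisland.genome import GenomeModel
from snpisland.simulate import SimConfig, make_linked_lines


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    """Six-arm model scaled to 1/20 of the full genome (desk scale)."""
    return GenomeModel().scaled(0.05)


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeModel:
    """Two short arms for fast unit tests."""
    return GenomeModel((("2L", 200_000), ("2R", 300_000)))


@pytest.fixture(scope="session")
def clean_dataset(small_genome):
    """One noise-free synthetic five-line dataset (session-cached)."""
    cfg = SimConfig(seed=7, fp_rate=0.0, fn_rate=0.0)
    return make_linked_lines(small_genome, cfg)
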