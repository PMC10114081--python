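import numpy as np
import pytest

from sigdissect.reference import ReferenceGenome, generate_reference


@pytest.fixture(scope="session")
def genome_100kb() -> ReferenceGenome:
    """One shared random genome large enough for context-dependent tests."""
    return generate_reference(100_000, n_contigs=2, gc_fraction=0.41, seed=20240901)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(77)


def make_genome(seq: str, name: str = "chr1") -> ReferenceGenome:
    """Tiny literal-sequence genome for worked examples."""
    return ReferenceGenome({name: seq})
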