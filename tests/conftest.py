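import numpy as np
import pytest

from aidsig import ReferenceSequence, SignatureSet, synthetic_signatures
from aidsig.catalog import CHANNELS, N_CHANNELS


@pytest.fixture(scope="session")
def sigs3() -> SignatureSet:
    """The package's three well-separated synthetic signatures."""
    return synthetic_signatures()


@pytest.fixture(scope="session")
def sigs_orthogonal() -> SignatureSet:
    """Two signatures with disjoint channel support (exact refits)."""
    a = np.zeros(N_CHANNELS)
    b = np.zeros(N_CHANNELS)
    a[:4] = 0.25
    b[50:52] = 0.5
    return SignatureSet(["A", "B"], np.column_stack([a, b]))


@pytest.fixture()
def tiny_genome() -> ReferenceSequence:
    #            123456789012345
    return ReferenceSequence({"chr1": "TACAGCATTNCGGCA", "chr2": "GGCCTTAA"})


def channel_of(five: str, ref: str, alt: str, three: str) -> int:
    return CHANNELS.index(f"{five}[{ref}>{alt}]{three}")
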