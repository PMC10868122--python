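import numpy as np
import pytest

from m1apred.seqio import RnaWindow, validate_window

BASES = "ACGU"


def random_window(rng: np.random.Generator, W: int = 41, id: str = "w") -> RnaWindow:
    """A uniformly random valid window: random bases, center forced to A."""
    bases = list(rng.choice(list(BASES), size=W))
    bases[(W - 1) // 2] = "A"
    return validate_window("".join(bases), W, id=id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def windows_small(rng):
    """20 random 41-nt windows."""
    return [random_window(rng, id=f"w{i}") for i in range(20)]
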