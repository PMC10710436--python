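import numpy as np
import pytest

from phasebench.gap_params import get_preset


@pytest.fixture
def point_c():
    return get_preset("C")


@pytest.fixture
def point_b():
    return get_preset("B")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
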