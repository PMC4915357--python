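import numpy as np
import pytest

from admixhist.io import QMatrix
from admixhist.simulate import desk_genome


@pytest.fixture(scope="session")
def genome():
    """Desk-scale validation genome: 8 x 128 cM, 256 windows per chromosome."""
    return desk_genome()


@pytest.fixture(scope="session")
def small_genome():
    """Tiny genome for fast I/O and pipeline tests."""
    return desk_genome(n_chromosomes=4, length_cm=64.0, windows=64)


@pytest.fixture()
def layered_q():
    """The 4-individual two-pulse construction: Q = ((1-c)a, (1-c)(1-a), c)
    with a and c exactly orthogonal, so cov(A/(A+B), C) vanishes."""
    a = np.array([0.2, 0.4, 0.6, 0.8])
    c = np.array([0.3, 0.1, 0.1, 0.3])
    q = np.column_stack([(1 - c) * a, (1 - c) * (1 - a), c])
    return QMatrix([f"ind{i}" for i in range(4)], ["A", "B", "C"], q)
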