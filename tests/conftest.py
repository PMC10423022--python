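import numpy as np
import pytest

from phdseg import BinaryMask, PointSet, generate_phantom


@pytest.fixture
def parallel_lines():
    """Two horizontal 1-px lines of length 20 in a 32x32 frame, offset by 6 rows."""
    a = np.zeros((32, 32), np.uint8)
    b = np.zeros((32, 32), np.uint8)
    a[10, 5:25] = 1
    b[16, 5:25] = 1
    return BinaryMask(a), BinaryMask(b)


@pytest.fixture
def ring():
    """A closed 8x8 square ring (1-px wide) in a 12x12 frame."""
    g = np.zeros((12, 12), np.uint8)
    g[2:10, 2:10] = 1
    g[3:9, 3:9] = 0
    return BinaryMask(g)


@pytest.fixture
def broken_ring(ring):
    g = ring.grid.copy()
    g[2, 5] = 0
    return BinaryMask(g)


@pytest.fixture
def phantom():
    return generate_phantom(42)


def random_pointset(rng, n_max=200, shape=(64, 64)):
    n = int(rng.integers(1, n_max + 1))
    coords = np.column_stack([rng.integers(0, shape[0], n), rng.integers(0, shape[1], n)])
    return PointSet(coords, shape)
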