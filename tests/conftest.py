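import numpy as np
import pytest

from mfmicd import BinaryNetwork, Partition


@pytest.fixture
def two_triangles() -> BinaryNetwork:
    """Two disjoint triangles: the classic Q = 0.5 graph."""
    return BinaryNetwork.from_edges(
        6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
    )


@pytest.fixture
def triangle_partition() -> Partition:
    return Partition.from_labels([0, 0, 0, 1, 1, 1])


@pytest.fixture
def bridged_triangles() -> BinaryNetwork:
    """Two triangles joined by a single bridge edge (2, 3)."""
    return BinaryNetwork.from_edges(
        6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
    )


def random_partition(rng: np.random.Generator, n: int) -> Partition:
    k = int(rng.integers(1, n + 1))
    labels = rng.integers(0, k, size=n)
    return Partition.from_labels(labels)
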