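import numpy as np
import pytest

from clonetrace.io import CellRecord, CloneMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def small_matrix():
    """3 clones x 2 cell types, hand-checkable."""
    return CloneMatrix(
        ["c1", "c2", "c3"],
        ["T1", "T2"],
        np.array([[2, 0], [1, 1], [0, 4]]),
    )


@pytest.fixture
def cells_with_clones():
    return [
        CellRecord("cell1", "T1", clone_id="c1"),
        CellRecord("cell2", "T1", clone_id="c1"),
        CellRecord("cell3", "T1", clone_id="c2"),
        CellRecord("cell4", "T2", clone_id="c2"),
        CellRecord("cell5", "T2", clone_id=None),
    ]


def random_clone_matrix(rng, n_clones=20, n_types=4, max_count=9):
    """Random CloneMatrix with guaranteed nonzero rows."""
    counts = rng.integers(0, max_count + 1, size=(n_clones, n_types))
    zero = counts.sum(axis=1) == 0
    counts[zero, 0] = 1
    return CloneMatrix(
        [f"c{i}" for i in range(n_clones)],
        [f"T{j}" for j in range(n_types)],
        counts,
    )
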