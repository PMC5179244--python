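import numpy as np
import pytest

from nbarscan import PresenceAbsenceMatrix


@pytest.fixture
def tri5():
    """5x5 strict subset chain: species i occupies sites 1..i."""
    return PresenceAbsenceMatrix(np.tril(np.ones((5, 5), dtype=int)))


@pytest.fixture
def ident5():
    """5x5 permutation matrix: no shared sites, no shared species."""
    return PresenceAbsenceMatrix(np.eye(5, dtype=int))


@pytest.fixture
def two_block():
    """Two disjoint blocks: species 1-3 on sites 1-5, species 4-6 on sites 6-10."""
    m = np.zeros((6, 10), dtype=int)
    m[:3, :5] = 1
    m[3:, 5:] = 1
    return PresenceAbsenceMatrix(m)


def random_pruned_matrix(rng, max_rows=8, max_cols=8, p=0.4):
    """Random 0/1 matrix with no empty rows/columns (resampled until valid)."""
    while True:
        r = rng.integers(2, max_rows + 1)
        c = rng.integers(2, max_cols + 1)
        m = (rng.random((r, c)) < p).astype(int)
        if m.sum(axis=1).min() > 0 and m.sum(axis=0).min() > 0:
            return PresenceAbsenceMatrix(m)
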