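import numpy as np
import pytest

from hdtv2 import linops as L


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def dense_matrix(op, shape):
    """Assemble the dense matrix of a linear operator column-by-column from impulses."""
    n = int(np.prod(shape))
    cols = []
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        cols.append(np.asarray(op(e.reshape(shape))).ravel())
    return np.array(cols).T


def random_mask(r, c, m, rng):
    """Random mask with exactly m selected coefficients, DC forced."""
    sel = np.zeros(r * c, dtype=bool)
    sel[rng.choice(r * c - 1, size=m - 1, replace=False) + 1] = True
    sel[0] = True
    return L.FourierMask(sel.reshape(r, c))
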