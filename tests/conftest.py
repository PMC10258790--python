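import numpy as np
import pytest

from chromarch import ContactMatrix


@pytest.fixture
def dense_matrix():
    """Build a ContactMatrix from a dense array (all bins unmasked)."""

    def build(values, bin_size=100_000, form="raw", chrom="chr1", mask=None):
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.ones(values.shape[0], dtype=bool)
        return ContactMatrix(chrom, bin_size, values, mask, form=form)

    return build


@pytest.fixture
def random_symmetric():
    """Random symmetric positive matrix with reproducible seeding."""

    def build(n, seed, low=0.5, high=2.0):
        rng = np.random.default_rng(seed)
        a = rng.uniform(low, high, (n, n))
        return (a + a.T) / 2.0

    return build
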