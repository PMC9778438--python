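import numpy as np
import pytest

from hicplaid import bin_genome
from hicplaid.contacts import ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bins5():
    """Single 5-bin chromosome at 1 Mb."""
    return bin_genome({"chrA": 5_000_000}, 1_000_000)


def symmetric_counts(rng, n, lam=5.0):
    """Random symmetric nonnegative integer matrix."""
    upper = np.triu(rng.poisson(lam, size=(n, n)).astype(float))
    return upper + np.triu(upper, 1).T


def make_matrix(values, resolution=1_000_000, chrom="chrA", kind="raw"):
    values = np.asarray(values, dtype=float)
    bins = bin_genome({chrom: values.shape[0] * resolution}, resolution)
    return ContactMatrix(bins, chrom, values, kind=kind)
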