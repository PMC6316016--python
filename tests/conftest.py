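import numpy as np
import pytest

from dupdiv.io import GenotypeMatrix


def make_matrix(calls, positions=None, pops=None, chrom="chr1", chrom_length=None):
    """Build a small GenotypeMatrix from a (sites x samples) dosage array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if positions is None:
        positions = np.arange(n_sites)
    if pops is None:
        pops = ["wild"] * n_samples
    ids = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions),
        ref=np.full(n_sites, "A"),
        alt=np.full(n_sites, "G"),
        calls=calls,
        sample_ids=ids,
        pop_map=dict(zip(ids, pops)),
        chrom_length=chrom_length,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n_samples=None, n_sites=None, missing_rate=0.05):
    """Random small genotype matrix, possibly with missing calls."""
    n_samples = n_samples or int(rng.integers(2, 11))
    n_sites = n_sites or int(rng.integers(1, 51))
    calls = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    mask = rng.random((n_sites, n_samples)) < missing_rate
    calls[mask] = -1
    positions = np.sort(rng.choice(1000, size=n_sites, replace=False))
    return make_matrix(calls, positions=positions, chrom_length=1000)
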