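import numpy as np
import pytest

from snpsample.genotype_io import MISSING, GenotypeMatrix


def make_matrix(calls, populations=None, samples=None, loci=None):
    """Build a GenotypeMatrix from a nested list (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    loci = loci or [f"L{j + 1}" for j in range(m)]
    if populations is None:
        populations = {s: "P1" for s in samples}
    elif isinstance(populations, (list, tuple)):
        populations = dict(zip(samples, populations))
    return GenotypeMatrix(
        samples=samples, loci=loci, populations=populations, calls=calls
    )


@pytest.fixture
def six_by_three():
    """6 diploid individuals x 3 loci, one population, fully typed."""
    return make_matrix(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, 1],
            [0, 2, 1],
            [1, 0, 0],
            [2, 1, 2],
        ]
    )


@pytest.fixture
def two_pop_matrix():
    """Two 4-individual populations over 5 loci with some missingness."""
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 3, size=(8, 5)).astype(np.int8)
    calls[0, 1] = MISSING
    calls[5, 3] = MISSING
    return make_matrix(calls, populations=["A"] * 4 + ["B"] * 4)


@pytest.fixture
def random_matrix():
    """4 populations x 6 individuals x 100 loci with 10% missingness."""
    rng = np.random.default_rng(7)
    calls = rng.integers(0, 3, size=(24, 100)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = MISSING
    pops = [f"P{k + 1}" for k in range(4) for _ in range(6)]
    return make_matrix(calls, populations=pops)
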