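import numpy as np
import pytest

from kinmate.io import AlleleFrequencySet, GenotypeTable, Individual


@pytest.fixture(scope="session")
def equifreq_panel() -> AlleleFrequencySet:
    """12 loci with 6 equifrequent alleles each — a maximally informative
    microsatellite panel used for calibration checks."""
    loci = [f"L{j + 1:02d}" for j in range(12)]
    return AlleleFrequencySet(
        loci,
        {l: {100 + 2 * i: 1 / 6 for i in range(6)} for l in loci},
        {l: 500 for l in loci},
    )


@pytest.fixture
def small_table() -> GenotypeTable:
    """Six adults, two loci, one missing genotype."""
    individuals = [
        Individual("f1", "female", frozenset({2010, 2011})),
        Individual("f2", "female", frozenset({2010})),
        Individual("f3", "female", frozenset({2011})),
        Individual("m1", "male", frozenset({2010, 2011})),
        Individual("m2", "male", frozenset({2010})),
        Individual("m3", "male", frozenset({2011})),
    ]
    geno = np.array(
        [
            [[101, 103], [201, 201]],
            [[101, 101], [201, 203]],
            [[103, 105], [203, 203]],
            [[101, 105], [201, 203]],
            [[103, 103], [-1, -1]],
            [[105, 105], [203, 205]],
        ],
        dtype=np.int64,
    )
    return GenotypeTable(individuals, ["locA", "locB"], geno)


def random_genotypes(
    freqs: AlleleFrequencySet, n: int, seed: int
) -> np.ndarray:
    """(n, L, 2) genotypes drawn independently from ``freqs`` (unrelated pool)."""
    rng = np.random.default_rng(seed)
    L = len(freqs.loci)
    out = np.empty((n, L, 2), dtype=np.int64)
    for j, locus in enumerate(freqs.loci):
        codes, p = freqs.codes(locus), freqs.probs(locus)
        out[:, j, :] = codes[rng.choice(len(codes), size=(n, 2), p=p)]
    return out
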