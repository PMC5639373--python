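import numpy as np
import pytest

from hetmate import GenotypeTable, allele_frequencies


def random_table(
    rng: np.random.Generator,
    n_individuals: int = 20,
    n_loci: int = 17,
    n_alleles: int = 8,
    missing_rate: float = 0.05,
) -> GenotypeTable:
    """A random HWE genotype table with sprinkled missing calls."""
    calls = rng.integers(1, n_alleles + 1, size=(n_individuals, n_loci, 2))
    miss = rng.random((n_individuals, n_loci)) < missing_rate
    calls[miss] = 0
    # keep every locus typed in at least one individual
    for j in range(n_loci):
        if (calls[:, j, 0] == 0).all():
            calls[0, j] = (1, 2)
    ids = [f"b{i:03d}" for i in range(n_individuals)]
    loci = [f"loc{j:02d}" for j in range(n_loci)]
    return GenotypeTable(ids, loci, calls)


@pytest.fixture(scope="session")
def small_table():
    return random_table(np.random.default_rng(77), n_individuals=30)


@pytest.fixture(scope="session")
def small_freqs(small_table):
    return allele_frequencies(small_table)


def brute_force_hl(table, freqs, individual):
    """Independent per-locus HL oracle: explicit loop, no array code shared
    with the implementation."""
    num = den = 0.0
    for locus in table.loci:
        a, b = table.genotype(individual, locus)
        if a == 0:
            continue
        p = freqs.frequencies(locus)
        e = 1.0 - sum(q * q for q in p.values())
        if e == 0.0:
            continue
        den += e
        if a == b:
            num += e
    return num / den if den > 0 else float("nan")
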