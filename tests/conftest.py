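import numpy as np
import pytest

from gprelate.grm import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_hwe_genotypes(n, m, rng, freqs=None):
    """Unrelated individuals at Hardy-Weinberg equilibrium."""
    if freqs is None:
        freqs = rng.uniform(0.1, 0.9, size=m)
    dos = rng.binomial(2, freqs, size=(n, m)).astype(float)
    ids = [f"ind{k}" for k in range(n)]
    return GenotypeMatrix(dos, ids, [f"s{k}" for k in range(m)])


def make_sib_families(n_families, sibs_per_family, m, rng, freqs=None):
    """Full-sib families: each family inherits from one parent pair.

    Returns (GenotypeMatrix, family_ids array).  Sib genotypes are built
    by transmitting one random allele per SNP from each parent, so full
    sibs have expected genomic relationship ~0.5.
    """
    if freqs is None:
        freqs = rng.uniform(0.1, 0.9, size=m)
    rows, fams = [], []
    for f in range(n_families):
        pat = rng.binomial(1, freqs, size=(2, m))  # two alleles per parent
        mat = rng.binomial(1, freqs, size=(2, m))
        for _ in range(sibs_per_family):
            a = pat[rng.integers(0, 2, size=m), np.arange(m)]
            b = mat[rng.integers(0, 2, size=m), np.arange(m)]
            rows.append(a + b)
            fams.append(f)
    dos = np.array(rows, dtype=float)
    ids = [f"f{f}_s{k}" for k, f in enumerate(fams)]
    return GenotypeMatrix(dos, ids, [f"s{k}" for k in range(m)]), np.array(fams)
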