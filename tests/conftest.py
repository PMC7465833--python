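import numpy as np
import pytest

from oleapop import GenotypeMatrix, PopulationPartition
from oleapop.io import IUPACSequenceSet


def random_matrix(rng, n_samples=8, n_loci=20, missing_rate=0.1):
    """Random biallelic genotype matrix (HWE within one pool)."""
    a1 = np.empty((n_samples, n_loci), dtype=np.int8)
    a2 = np.empty((n_samples, n_loci), dtype=np.int8)
    for j in range(n_loci):
        pair = rng.choice(4, size=2, replace=False)
        p = rng.uniform(0.1, 0.9)
        dos = rng.binomial(2, p, size=n_samples)
        hi = np.where(dos >= 1, pair[0], pair[1])
        lo = np.where(dos == 2, pair[0], pair[1])
        a1[:, j] = np.minimum(hi, lo)
        a2[:, j] = np.maximum(hi, lo)
    if missing_rate > 0:
        mask = rng.random((n_samples, n_loci)) < missing_rate
        a1[mask] = -1
        a2[mask] = -1
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        locus_ids=[f"loc{j}" for j in range(n_loci)],
        allele1=a1,
        allele2=a2,
    )


def random_iupac_seqs(rng, n=8, L=40, chars="ACGTRYSWKMN"):
    codes = rng.choice([ord(c) for c in chars], size=(n, L)).astype(np.uint8)
    return IUPACSequenceSet(
        sample_ids=[f"s{i}" for i in range(n)],
        locus_ids=[f"p{j}" for j in range(L)],
        codes=codes,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 loci with one het and one missing call."""
    from oleapop.io import _CODE

    def enc(call):
        if call == "NN":
            return (-1, -1)
        a, b = sorted(_CODE[c] for c in call)
        return (a, b)

    calls = [["AA", "CC"], ["AG", "CC"], ["NN", "CT"]]
    a1 = np.array([[enc(c)[0] for c in row] for row in calls], dtype=np.int8)
    a2 = np.array([[enc(c)[1] for c in row] for row in calls], dtype=np.int8)
    m = GenotypeMatrix(["x", "y", "z"], ["l1", "l2"], a1, a2)
    p = PopulationPartition({"x": "CULTIVAR", "y": "CULTIVAR", "z": "WILD"})
    return m, p
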