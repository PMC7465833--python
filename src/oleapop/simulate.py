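"""Synthetic EST-SNP genotype matrices with planted divergent loci.

The generator emulates the structure of a three-population olive panel
(cultivated, wild/oleaster, Canary-island *guanchica*): biallelic loci with
population-specific drift under the Balding-Nichols model, a subset of loci
planted near-fixed for opposite homozygotes between chosen groups, optional
admixed individuals, and sporadic missing calls.  All randomness flows from a
single seed through one generator.

Non-planted loci draw an ancestral frequency p0 ~ Uniform(0.05, 0.95) and
per-group frequencies p_g ~ Beta(p0(1-F_g)/F_g, (1-p0)(1-F_g)/F_g), then
genotypes binomially under Hardy-Weinberg.  Planted loci fix the contrasted
groups at allele frequencies (1 +/- delta)/2 and are drawn with quasi-exact
Hardy-Weinberg genotype composition (largest-remainder rounding of the
expected genotype counts, randomly permuted over samples) so that the
realised homozygote-frequency contrast stays within O(1/n) of delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    GenotypeMatrix,
    PopulationPartition,
    CULTIVAR,
    WILD,
    GUANCHICA,
)
from .effects import Transcript

#: proportions of the three hit categories among planted loci, mirroring the
#: observed 72 : 24 : 28 split (focal vs both / vs wild only / vs guanchica only)
DEFAULT_CATEGORY_WEIGHTS = (72, 24, 28)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genotype panel.

    ``drift`` holds one Balding-Nichols differentiation parameter per group in
    the open interval (0, 1); defaults reflect a large admixed cultivated gene
    pool, a moderately drifted wild population and a small island-endemic
    group, at magnitudes consistent with a <=1% screen false-positive rate on
    null loci.
    """

    group_sizes: tuple[int, ...] = (171, 73, 16)
    group_labels: tuple[str, ...] = (CULTIVAR, WILD, GUANCHICA)
    n_loci: int = 1040
    drift: tuple[float, ...] = (0.02, 0.03, 0.05)
    n_planted: int = 124
    planted_delta: float = 0.75
    planted_categories: tuple[str, ...] | None = None
    missing_rate: float = 0.02
    admixture_fraction: float = 0.0
    seed: int = 0

    def categories(self) -> tuple[str, str, str]:
        f, w, g = self.group_labels
        return (f"{f}_vs_BOTH", f"{f}_vs_{w}", f"{f}_vs_{g}")

    def validate(self) -> None:
        if len(self.group_sizes) != 3 or len(self.group_labels) != 3:
            raise ValueError("exactly three groups are required")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError(f"group sizes must be >= 1, got {self.group_sizes}")
        if len(self.drift) != 3 or any(not 0 < f < 1 for f in self.drift):
            raise ValueError(f"drift must be three values in (0, 1), got {self.drift}")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0 <= self.planted_delta <= 1:
            raise ValueError(f"planted_delta must be in [0, 1], got {self.planted_delta}")
        if not 0 <= self.n_planted <= self.n_loci:
            raise ValueError("n_planted must be in [0, n_loci]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not 0 <= self.admixture_fraction <= 1:
            raise ValueError("admixture_fraction must be in [0, 1]")
        if self.planted_categories is not None:
            if len(self.planted_categories) != self.n_planted:
                raise ValueError("planted_categories length must equal n_planted")
            bad = set(self.planted_categories) - set(self.categories())
            if bad:
                raise ValueError(f"unknown planted categories: {sorted(bad)}")


@dataclass
class PlantedTruth:
    """Ground truth for the planted divergent loci."""

    locus_ids: list[str]
    categories: list[str]
    genotype_focal: list[str]  # homozygote planted in the focal group
    genotype_contrast: list[str]  # opposite homozygote in contrasted group(s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "category": self.categories,
                "genotype_A": self.genotype_focal,
                "genotype_B": self.genotype_contrast,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _largest_remainder(n: int, probs: np.ndarray) -> np.ndarray:
    """Integer counts summing to n, proportional to probs (largest remainder)."""
    raw = n * probs
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base


def _split_categories(n: int, cats: tuple[str, str, str]) -> list[str]:
    w = np.array(DEFAULT_CATEGORY_WEIGHTS, dtype=float)
    counts = _largest_remainder(n, w / w.sum())
    out: list[str] = []
    for c, k in zip(cats, counts):
        out.extend([c] * int(k))
    return out


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationPartition, PlantedTruth]:
    """Generate a genotype matrix, its population labels and planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_groups = 3
    sizes = config.group_sizes
    labels = config.group_labels
    n_total = sum(sizes)
    L = config.n_loci

    prefixes = [lab[:4].upper() for lab in labels]
    sample_ids: list[str] = []
    pop_labels: dict[str, str] = {}
    group_index = np.empty(n_total, dtype=int)
    pos = 0
    for g, (lab, size, pre) in enumerate(zip(labels, sizes, prefixes)):
        for i in range(size):
            sid = f"{pre}{i + 1:03d}"
            sample_ids.append(sid)
            pop_labels[sid] = lab
            group_index[pos] = g
            pos += 1
    locus_ids = [f"L{j + 1:04d}" for j in range(L)]

    # locus alleles: two distinct bases per locus
    allele_pairs = np.array([rng.choice(4, size=2, replace=False) for _ in range(L)])

    planted_idx = np.sort(rng.choice(L, size=config.n_planted, replace=False))
    cats = config.categories()
    if config.planted_categories is not None:
        planted_cats = list(config.planted_categories)
    else:
        planted_cats = _split_categories(config.n_planted, cats)
    contrasted_by_cat = {cats[0]: (1, 2), cats[1]: (1,), cats[2]: (2,)}

    # per-group frequency of allele_pairs[:, 0] at every locus
    p0 = rng.uniform(0.05, 0.95, size=L)
    freqs = np.empty((n_groups, L))
    for g in range(n_groups):
        F = config.drift[g]
        a = p0 * (1 - F) / F
        b = (1 - p0) * (1 - F) / F
        freqs[g] = rng.beta(a, b)
    planted_set = set(int(i) for i in planted_idx)
    for j, cat in zip(planted_idx, planted_cats):
        hi = (1 + config.planted_delta) / 2
        lo = (1 - config.planted_delta) / 2
        contrasted = contrasted_by_cat[cat]
        freqs[0, j] = hi
        for g in (1, 2):
            freqs[g, j] = lo if g in contrasted else hi

    # admixed samples: both alleles from a 50/50 mixture of two group pools
    n_admixed = int(round(config.admixture_fraction * n_total))
    admixed = rng.choice(n_total, size=n_admixed, replace=False) if n_admixed else np.empty(0, dtype=int)
    partner = np.full(n_total, -1, dtype=int)
    for s in admixed:
        others = [g for g in range(n_groups) if g != group_index[s]]
        partner[s] = rng.choice(others)

    dosage = np.empty((n_total, L), dtype=np.int8)  # count of allele_pairs[:,0]
    sample_p = freqs[group_index]  # (n_total, L)
    mix = partner >= 0
    if mix.any():
        sample_p[mix] = 0.5 * (freqs[group_index[mix]] + freqs[partner[mix]])
    dosage[:] = rng.binomial(2, sample_p)

    # planted loci: quasi-exact HWE composition per group, permuted over samples
    group_slices = []
    start = 0
    for size in sizes:
        group_slices.append(np.arange(start, start + size))
        start += size
    for j in planted_idx:
        for g in range(n_groups):
            p = freqs[g, j]
            probs = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
            counts = _largest_remainder(sizes[g], probs)
            col = np.repeat([2, 1, 0], counts).astype(np.int8)
            dosage[group_slices[g], j] = rng.permutation(col)

    # dosage counts allele_pairs[:,0]; translate to sorted nucleotide pairs
    first = allele_pairs[:, 0][None, :].astype(np.int8)
    second = allele_pairs[:, 1][None, :].astype(np.int8)
    a_hi = np.where(dosage >= 1, first, second)  # one copy of first if dosage>=1
    a_lo = np.where(dosage == 2, first, second)
    allele1 = np.minimum(a_hi, a_lo).astype(np.int8)
    allele2 = np.maximum(a_hi, a_lo).astype(np.int8)

    if config.missing_rate > 0:
        mask = rng.random((n_total, L)) < config.missing_rate
        allele1[mask] = -1
        allele2[mask] = -1

    matrix = GenotypeMatrix(sample_ids, locus_ids, allele1, allele2)
    partition = PopulationPartition(pop_labels)

    from .io import NUCLEOTIDES

    truth = PlantedTruth(
        locus_ids=[locus_ids[j] for j in planted_idx],
        categories=list(planted_cats),
        genotype_focal=[NUCLEOTIDES[allele_pairs[j, 0]] * 2 for j in planted_idx],
        genotype_contrast=[NUCLEOTIDES[allele_pairs[j, 1]] * 2 for j in planted_idx],
    )
    return matrix, partition, truth


# ---------------------------------------------------------------------------
# toy transcripts with planted SNPs of known effect class


# codon pairs guaranteed synonymous (four-fold degenerate third positions)
_S_PAIRS = [("GCT", "GCC"), ("GGA", "GGG"), ("CTT", "CTC"), ("GTA", "GTG"), ("TCT", "TCA")]
# codon pairs guaranteed non-synonymous (known residue changes)
_NS_PAIRS = [
    ("GAT", "GAA"),  # Asp -> Glu
    ("AGA", "AAA"),  # Arg -> Lys
    ("TTT", "TGT"),  # Phe -> Cys
    ("CAT", "CGT"),  # His -> Arg
    ("GCT", "ACT"),  # Ala -> Thr
]


def simulate_transcripts(
    n: int, seed: int = 0
) -> tuple[dict[str, Transcript], pd.DataFrame]:
    """Random transcripts, each carrying one SNP of known class.

    Returns the transcripts and a truth table with columns transcript,
    position, ref, alt, expected_class (UTR / sSNP / nsSNP), derived by
    construction (synonymous pairs come from four-fold degenerate codon
    families, non-synonymous pairs from fixed residue-changing codon pairs).
    """
    if n < 1:
        raise ValueError(f"need n >= 1 transcripts, got {n}")
    rng = np.random.default_rng(seed)
    kinds = ["UTR5", "sSNP", "nsSNP", "UTR3"]
    transcripts: dict[str, Transcript] = {}
    rows = []
    for i in range(n):
        utr5 = int(rng.integers(20, 80))
        n_codons = int(rng.integers(30, 70))
        utr3 = int(rng.integers(20, 80))
        length = utr5 + 3 * n_codons + utr3
        seq = list("ACGT"[c] for c in rng.integers(0, 4, size=length))
        cds_start = utr5 + 1
        cds_end = utr5 + 3 * n_codons
        kind = kinds[i % len(kinds)]
        if kind in ("UTR5", "UTR3"):
            if kind == "UTR5":
                position = int(rng.integers(1, cds_start))
            else:
                position = int(rng.integers(cds_end + 1, length + 1))
            ref = seq[position - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            expected = "UTR"
        else:
            pairs = _S_PAIRS if kind == "sSNP" else _NS_PAIRS
            ref_codon, alt_codon = pairs[int(rng.integers(0, len(pairs)))]
            codon_i = int(rng.integers(0, n_codons))
            codon_pos0 = utr5 + 3 * codon_i
            seq[codon_pos0 : codon_pos0 + 3] = list(ref_codon)
            offset = next(
                k for k in range(3) if ref_codon[k] != alt_codon[k]
            )
            position = codon_pos0 + offset + 1
            ref, alt = ref_codon[offset], alt_codon[offset]
            expected = kind
        tid = f"contig{i + 1:04d}"
        transcripts[tid] = Transcript(tid, "".join(seq), cds_start, cds_end)
        rows.append(
            {
                "transcript": tid,
                "position": position,
                "ref": ref,
                "alt": str(alt),
                "expected_class": expected,
            }
        )
    return transcripts, pd.DataFrame(rows)
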