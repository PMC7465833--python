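"""Genotype matrices, IUPAC concatenation, site filtering and on-disk formats.

The on-disk genotype format is a wide codominant table (one row per sample,
column 2 = population label, one column per locus, calls written as two-letter
strings such as ``AG``), the layout used by codominant-marker tool chains.
Heterozygous calls are stored unordered: phase is unknown for EST-SNP panels
and irrelevant to every statistic computed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}
MISSING = -1

#: canonical group labels for the olive panel
CULTIVAR = "CULTIVAR"
WILD = "WILD"
GUANCHICA = "GUANCHICA"

#: unordered diploid call -> IUPAC one-letter code
IUPAC_FROM_PAIR = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}
PAIR_FROM_IUPAC = {v: k for k, v in IUPAC_FROM_PAIR.items()}

#: every IUPAC nucleotide code -> set of bases it denotes (N/gap excluded)
IUPAC_SETS = dict(
    PAIR_FROM_IUPAC,
    B=frozenset("CGT"),
    D=frozenset("AGT"),
    H=frozenset("ACT"),
    V=frozenset("ACG"),
)

_MISSING_TOKENS = {"NN", "--", "", "N", "-", "??", "0", "NA"}


class GenotypeError(ValueError):
    """Raised when a genotype table or matrix violates the panel invariants."""


@dataclass
class GenotypeMatrix:
    """Diploid nucleotide calls for a biallelic SNP panel.

    ``allele1``/``allele2`` are (n_samples, n_loci) int8 arrays with base codes
    A,C,G,T = 0..3 and ``MISSING`` (-1) in both slots for untyped calls.
    Calls are order-normalised so that ``allele1 <= allele2``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.sample_ids), len(self.locus_ids)
        if len(set(self.sample_ids)) != n:
            raise GenotypeError("duplicate sample ids")
        if len(set(self.locus_ids)) != m:
            raise GenotypeError("duplicate locus ids")
        for arr in (self.allele1, self.allele2):
            if arr.shape != (n, m):
                raise GenotypeError(
                    f"call array shape {arr.shape} != ({n}, {m})"
                )
        miss1 = self.allele1 == MISSING
        miss2 = self.allele2 == MISSING
        if not np.array_equal(miss1, miss2):
            raise GenotypeError("half-missing calls are not representable")
        ok = miss1 | (
            (self.allele1 >= 0) & (self.allele1 <= 3)
            & (self.allele2 >= 0) & (self.allele2 <= 3)
            & (self.allele1 <= self.allele2)
        )
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise GenotypeError(
                f"invalid call at sample {self.sample_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r}"
            )
        self._check_biallelic()

    def _check_biallelic(self) -> None:
        a1, a2 = self.allele1, self.allele2
        bad = []
        for j in range(self.n_loci):
            col = np.concatenate([a1[:, j], a2[:, j]])
            alleles = np.unique(col[col >= 0])
            if alleles.size > 2:
                bad.append((self.locus_ids[j],
                            "/".join(NUCLEOTIDES[a] for a in alleles)))
        if bad:
            head = ", ".join(f"{lid} ({obs})" for lid, obs in bad[:5])
            raise GenotypeError(
                f"{len(bad)} loci exceed 2 alleles (biallelic panel): {head}"
            )

    # -- basic views -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci), True where the call is missing."""
        return self.allele1 == MISSING

    def locus_alleles(self) -> np.ndarray:
        """(n_loci, 2) int8: sorted allele codes per locus, -1 when absent."""
        out = np.full((self.n_loci, 2), MISSING, dtype=np.int8)
        for j in range(self.n_loci):
            col = np.concatenate([self.allele1[:, j], self.allele2[:, j]])
            alleles = np.unique(col[col >= 0])
            out[j, : alleles.size] = alleles
        return out

    def dosage(self) -> np.ndarray:
        """Count of the lexicographically larger (alt) allele: 0/1/2, NaN missing.

        REF is the lexicographically smaller allele at each locus, matching the
        VCF export convention.
        """
        ref = self.locus_alleles()[:, 0].astype(np.int16)
        dos = (self.allele1 != ref[None, :]).astype(float) + (
            self.allele2 != ref[None, :]
        )
        dos[self.missing_mask] = np.nan
        return dos

    def calls_str(self) -> np.ndarray:
        """(n_samples, n_loci) array of two-letter call strings, 'NN' if missing."""
        out = np.empty((self.n_samples, self.n_loci), dtype=object)
        for i in range(self.n_samples):
            for j in range(self.n_loci):
                a, b = self.allele1[i, j], self.allele2[i, j]
                out[i, j] = "NN" if a == MISSING else NUCLEOTIDES[a] + NUCLEOTIDES[b]
        return out

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(
            sample_ids=list(ids),
            locus_ids=list(self.locus_ids),
            allele1=self.allele1[idx].copy(),
            allele2=self.allele2[idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.allele1, other.allele1)
            and np.array_equal(self.allele2, other.allele2)
        )


@dataclass
class PopulationPartition:
    """Mapping of every sample to exactly one population label."""

    labels: dict[str, str]

    def group_of(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.labels.items():
            out.setdefault(g, []).append(s)
        return out

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.labels.values():
            if g not in seen:
                seen.append(g)
        return seen

    def indices(self, sample_ids: list[str], group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(sample_ids) if self.labels[s] == group],
            dtype=int,
        )

    def validate_against(self, matrix: GenotypeMatrix, min_per_group: int = 2) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.labels]
        if missing:
            raise GenotypeError(f"samples without a population label: {missing[:5]}")
        for g, members in self.groups().items():
            if len(members) < min_per_group:
                raise GenotypeError(
                    f"group {g!r} has {len(members)} samples (< {min_per_group})"
                )


@dataclass
class IUPACSequenceSet:
    """One IUPAC-coded pseudo-sequence per sample, over a shared locus order."""

    sample_ids: list[str]
    locus_ids: list[str]
    codes: np.ndarray  # (n, L) uint8 ASCII codes
    n_removed_sites: int = 0

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise GenotypeError("sequence array shape inconsistent with ids")

    @property
    def n_sequences(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.locus_ids)

    def sequences(self) -> list[str]:
        return [bytes(row).decode("ascii") for row in self.codes]

    @classmethod
    def from_strings(
        cls, sample_ids: list[str], seqs: list[str], locus_ids: list[str] | None = None
    ) -> "IUPACSequenceSet":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise GenotypeError("sequences differ in length")
        L = lengths.pop() if lengths else 0
        if locus_ids is None:
            locus_ids = [f"pos{i + 1}" for i in range(L)]
        codes = np.frombuffer(
            "".join(s.upper() for s in seqs).encode("ascii"), dtype=np.uint8
        ).reshape(len(seqs), L).copy()
        return cls(sample_ids=list(sample_ids), locus_ids=list(locus_ids), codes=codes)

    def take(self, sample_ids: list[str]) -> "IUPACSequenceSet":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return IUPACSequenceSet(
            sample_ids=list(sample_ids),
            locus_ids=list(self.locus_ids),
            codes=self.codes[idx].copy(),
        )


# ---------------------------------------------------------------------------
# genotype table I/O


def _parse_call(token: str, sample: str, locus: str) -> tuple[int, int]:
    token = token.strip().upper()
    if token in _MISSING_TOKENS:
        return MISSING, MISSING
    if len(token) != 2 or any(c not in _CODE for c in token):
        raise GenotypeError(
            f"unparseable call {token!r} at sample {sample!r}, locus {locus!r}"
        )
    a, b = sorted(_CODE[c] for c in token)
    return a, b


def read_genotype_table(
    path, *, delimiter: str | None = None, pop_column: str | int = 1
) -> tuple[GenotypeMatrix, PopulationPartition]:
    """Read a wide codominant genotype table.

    Column 1 holds sample ids, ``pop_column`` (name or 0-based position among
    the non-id columns) the population label, remaining columns one locus each.
    """
    if delimiter is None:
        delimiter = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=delimiter, dtype=str, index_col=0, keep_default_na=False)
    if isinstance(pop_column, int):
        pop_name = df.columns[pop_column - 1] if pop_column >= 1 else df.columns[0]
    else:
        pop_name = pop_column
    if pop_name not in df.columns:
        raise GenotypeError(f"population column {pop_name!r} not found")
    labels = {str(s): str(g) for s, g in df[pop_name].items()}
    loci = [c for c in df.columns if c != pop_name]
    samples = [str(s) for s in df.index]
    if len(set(samples)) != len(samples):
        raise GenotypeError("duplicate sample ids in table")
    n, m = len(samples), len(loci)
    a1 = np.full((n, m), MISSING, dtype=np.int8)
    a2 = np.full((n, m), MISSING, dtype=np.int8)
    for j, locus in enumerate(loci):
        col = df[locus].to_numpy()
        for i, token in enumerate(col):
            a1[i, j], a2[i, j] = _parse_call(str(token), samples[i], locus)
    matrix = GenotypeMatrix(samples, loci, a1, a2)
    part = PopulationPartition(labels)
    n_missing = int(matrix.missing_mask.sum())
    logger.info(
        "read %d samples x %d loci (%d missing calls) from %s",
        n, m, n_missing, path,
    )
    return matrix, part


def write_genotype_table(
    matrix: GenotypeMatrix,
    partition: PopulationPartition,
    path,
    *,
    delimiter: str = "\t",
) -> None:
    calls = matrix.calls_str()
    df = pd.DataFrame(calls, index=matrix.sample_ids, columns=matrix.locus_ids)
    df.insert(0, "population", [partition.group_of(s) for s in matrix.sample_ids])
    df.index.name = "sample"
    df.to_csv(path, sep=delimiter)


# ---------------------------------------------------------------------------
# IUPAC concatenation and the site-coverage filter


def concatenate_iupac(matrix: GenotypeMatrix) -> IUPACSequenceSet:
    """Collapse each diploid call to one IUPAC character per locus.

    Homozygotes map to the base itself, heterozygotes to the two-base
    ambiguity code, missing calls to N; locus order is preserved.
    """
    lut = np.empty((5, 5), dtype=np.uint8)  # index MISSING via slot 4
    lut[:] = ord("N")
    for pair, char in IUPAC_FROM_PAIR.items():
        codes = sorted(_CODE[c] for c in pair)
        a = codes[0]
        b = codes[-1]
        lut[a, b] = ord(char)
    a1 = np.where(matrix.allele1 == MISSING, 4, matrix.allele1)
    a2 = np.where(matrix.allele2 == MISSING, 4, matrix.allele2)
    codes = lut[a1, a2]
    return IUPACSequenceSet(
        sample_ids=list(matrix.sample_ids),
        locus_ids=list(matrix.locus_ids),
        codes=codes,
    )


def filter_sites(
    seqs: IUPACSequenceSet, min_coverage: float = 0.95
) -> IUPACSequenceSet:
    """Drop positions whose fraction of non-N characters is below ``min_coverage``.

    The boundary is inclusive: a site with coverage exactly ``min_coverage``
    is retained.  Idempotent.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError(f"min_coverage must be in (0, 1], got {min_coverage}")
    coverage = (seqs.codes != ord("N")).mean(axis=0)
    keep = coverage >= min_coverage
    if not keep.any():
        raise GenotypeError(
            f"all {seqs.length} sites fall below {min_coverage:.0%} coverage"
        )
    removed = int((~keep).sum())
    if removed:
        logger.info("site-coverage filter removed %d of %d sites", removed, seqs.length)
    return IUPACSequenceSet(
        sample_ids=list(seqs.sample_ids),
        locus_ids=[l for l, k in zip(seqs.locus_ids, keep) if k],
        codes=seqs.codes[:, keep].copy(),
        n_removed_sites=seqs.n_removed_sites + removed,
    )


# ---------------------------------------------------------------------------
# FASTA / Newick / VCF writers


def write_fasta(seqs: IUPACSequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(seqs.sample_ids, seqs.sequences())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> IUPACSequenceSet:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return IUPACSequenceSet.from_strings(ids, seqs)


def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        nwk = str(tree).strip()
        if not nwk.endswith(";"):
            nwk += ";"
        fh.write(nwk + "\n")


def write_vcf(matrix: GenotypeMatrix, path, *, contig: str = "estsnp_panel") -> None:
    """Minimal VCF 4.2 export on one pseudo-contig.

    Loci are unanchored EST markers, so positions are 1-based consecutive
    indices; REF is the lexicographically smaller observed allele.
    """
    alleles = matrix.locus_alleles()
    dos = matrix.dosage()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={matrix.n_loci}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, locus in enumerate(matrix.locus_ids):
            ref_code, alt_code = alleles[j]
            if ref_code == MISSING:  # fully untyped locus
                ref, alt = "N", "."
            else:
                ref = NUCLEOTIDES[ref_code]
                alt = NUCLEOTIDES[alt_code] if alt_code != MISSING else "."
            gts = [
                "./." if np.isnan(d) else gt_map[d] for d in dos[:, j]
            ]
            fh.write(
                f"{contig}\t{j + 1}\t{locus}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
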