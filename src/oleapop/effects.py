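"""Translation-based SNP effect classification on transcript contigs.

Transcripts are sense-strand mRNA (EST contigs) with 1-based inclusive CDS
bounds.  A SNP inside the CDS is classified by translating the reference and
alternate codons with the standard genetic code: synonymous (sSNP) when the
residue is unchanged, non-synonymous (nsSNP) otherwise, with stop-codon gain
or loss flagged.  SNPs outside the CDS are UTR variants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

REGION_UTR5 = "UTR5"
REGION_CDS = "CDS"
REGION_UTR3 = "UTR3"

CLASS_S = "sSNP"
CLASS_NS = "nsSNP"
CLASS_UTR = "UTR"


@dataclass
class Transcript:
    """Sense-strand transcript with 1-based inclusive CDS coordinates."""

    id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        L = len(self.sequence)
        if not (1 <= self.cds_start <= self.cds_end <= L):
            raise ValueError(
                f"transcript {self.id!r}: CDS [{self.cds_start}, {self.cds_end}] "
                f"outside sequence of length {L}"
            )
        cds_len = self.cds_end - self.cds_start + 1
        if cds_len % 3:
            raise ValueError(
                f"transcript {self.id!r}: CDS length {cds_len} not divisible by 3"
            )


@dataclass
class SnpEffect:
    transcript_id: str
    position: int  # 1-based on the transcript
    ref: str
    alt: str
    region: str
    codon_index: int | None  # 0-based codon within the CDS
    codon_offset: int | None  # 0, 1 or 2
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str | None
    alt_aa: str | None
    effect_class: str
    stop_changed: bool = False


def classify_snp(t: Transcript, position: int, ref: str, alt: str) -> SnpEffect:
    """Classify one SNP on a transcript as UTR, sSNP or nsSNP."""
    ref, alt = ref.upper(), alt.upper()
    if not 1 <= position <= len(t.sequence):
        raise ValueError(
            f"position {position} outside transcript {t.id!r} "
            f"(length {len(t.sequence)})"
        )
    observed = t.sequence[position - 1]
    if observed != ref:
        raise ValueError(
            f"reference allele mismatch at {t.id!r}:{position}: "
            f"sequence has {observed!r}, SNP says {ref!r}"
        )
    if position < t.cds_start:
        region = REGION_UTR5
    elif position > t.cds_end:
        region = REGION_UTR3
    else:
        region = REGION_CDS
    if region != REGION_CDS:
        return SnpEffect(
            transcript_id=t.id, position=position, ref=ref, alt=alt,
            region=region, codon_index=None, codon_offset=None,
            ref_codon=None, alt_codon=None, ref_aa=None, alt_aa=None,
            effect_class=CLASS_UTR,
        )
    off_in_cds = position - t.cds_start
    codon_index = off_in_cds // 3
    codon_offset = off_in_cds % 3
    codon_start = t.cds_start - 1 + 3 * codon_index
    ref_codon = t.sequence[codon_start : codon_start + 3]
    alt_codon = (
        ref_codon[:codon_offset] + alt + ref_codon[codon_offset + 1 :]
    )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    synonymous = ref_aa == alt_aa
    stop_changed = ("*" in (ref_aa, alt_aa)) and not synonymous
    return SnpEffect(
        transcript_id=t.id, position=position, ref=ref, alt=alt,
        region=region, codon_index=codon_index, codon_offset=codon_offset,
        ref_codon=ref_codon, alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa,
        effect_class=CLASS_S if synonymous else CLASS_NS,
        stop_changed=stop_changed,
    )


def tally_effects(effects: list[SnpEffect]) -> dict[str, int]:
    """Counts of sSNP / nsSNP / UTR classes; always includes all three keys."""
    counts = Counter(e.effect_class for e in effects)
    return {c: counts.get(c, 0) for c in (CLASS_S, CLASS_NS, CLASS_UTR)}


def effects_frame(effects: list[SnpEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript": e.transcript_id,
                "position": e.position,
                "ref": e.ref,
                "alt": e.alt,
                "region": e.region,
                "ref_codon": e.ref_codon,
                "alt_codon": e.alt_codon,
                "ref_aa": e.ref_aa,
                "alt_aa": e.alt_aa,
                "class": e.effect_class,
                "stop_changed": e.stop_changed,
            }
            for e in effects
        ]
    )


# ---------------------------------------------------------------------------
# transcript + CDS table I/O and annotation join


def read_transcripts(fasta_path, cds_table_path) -> dict[str, Transcript]:
    """Load transcripts from FASTA plus a TSV of (id, cds_start, cds_end)."""
    cds = pd.read_csv(cds_table_path, sep="\t", dtype={"id": str})
    bounds = {
        str(r["id"]): (int(r["cds_start"]), int(r["cds_end"]))
        for _, r in cds.iterrows()
    }
    out: dict[str, Transcript] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in bounds:
            raise ValueError(f"transcript {rec.id!r} missing from CDS table")
        s, e = bounds[rec.id]
        out[rec.id] = Transcript(rec.id, str(rec.seq), s, e)
    return out


def write_transcripts(transcripts: dict[str, Transcript], fasta_path, cds_table_path) -> None:
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts.values()],
        str(fasta_path),
        "fasta",
    )
    pd.DataFrame(
        [
            {"id": t.id, "cds_start": t.cds_start, "cds_end": t.cds_end}
            for t in transcripts.values()
        ]
    ).to_csv(cds_table_path, sep="\t", index=False)


def load_annotation(path) -> pd.DataFrame:
    """Pre-made annotation table: locus -> gene name and GO terms (TSV)."""
    annot = pd.read_csv(path, sep="\t", dtype=str)
    if "locus" not in annot.columns:
        raise ValueError("annotation table needs a 'locus' column")
    return annot


def join_annotation(hits: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Left-join screen hits with an external gene/GO annotation table."""
    return hits.merge(annotation, on="locus", how="left")
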