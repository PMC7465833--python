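"""Opposite-homozygosity divergence screen for candidate domestication loci.

Each diploid call is merged to one of three haploid-style states (the two
homozygotes and the heterozygote).  A locus is a hit for a contrast
(focal, other) when the predominant homozygote differs between the two
groups and the focal group's major-homozygote frequency exceeds that
genotype's frequency in the other group by at least the threshold
(default 45%, inclusive).  Hits are classified by which contrasts passed:
both contrasts, or only one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, NUCLEOTIDES, GenotypeMatrix, PopulationPartition

CATEGORY_BOTH = "BOTH"


@dataclass
class ScreenHit:
    """One locus passing the screen, with its category and evidence."""

    locus_id: str
    category: str  # "<focal>_vs_BOTH" or "<focal>_vs_<other>"
    contrasted_genotypes: tuple[str, str]  # focal-major, other-major
    frequencies: dict[str, dict[str, float]]  # group -> {hom1, hom2, het}
    differences: dict[str, float]  # other group -> signed frequency difference


@dataclass
class ScreenResult:
    hits: list[ScreenHit]
    counts: dict[str, int]
    skipped_loci: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hits:
            row = {
                "locus": h.locus_id,
                "category": h.category,
                "focal_major": h.contrasted_genotypes[0],
                "other_major": h.contrasted_genotypes[1],
            }
            for g, freqs in h.frequencies.items():
                for state, f in freqs.items():
                    row[f"f_{state}_{g}"] = f
            for g, d in h.differences.items():
                row[f"diff_vs_{g}"] = d
            rows.append(row)
        return pd.DataFrame(rows)


def homozygote_profile(
    matrix: GenotypeMatrix, partition: PopulationPartition
) -> pd.DataFrame:
    """Per (locus, group) frequencies of the merged haploid-style states.

    Columns: alleles (lexicographic ``hom1``/``hom2`` base), ``f_hom1``,
    ``f_hom2``, ``f_het``, ``f_missing``, ``n_typed``, ``major`` (the
    predominant homozygous genotype, lexicographic on ties).  Frequencies are
    over typed samples; a locus untyped in a group gets NaN frequencies.
    """
    alleles = matrix.locus_alleles()
    dos = matrix.dosage()
    records = []
    for group in partition.group_names():
        idx = partition.indices(matrix.sample_ids, group)
        if idx.size == 0:
            raise ValueError(f"group {group!r} is empty")
        sub = dos[idx]
        n_group = idx.size
        for j, locus in enumerate(matrix.locus_ids):
            a1, a2 = alleles[j]
            hom1 = NUCLEOTIDES[a1] * 2 if a1 != MISSING else None
            hom2 = NUCLEOTIDES[a2] * 2 if a2 != MISSING else None
            col = sub[:, j]
            typed = col[~np.isnan(col)]
            n_typed = typed.size
            if n_typed == 0:
                f1 = f2 = fh = np.nan
                major = None
            else:
                f1 = float((typed == 0).mean())
                f2 = float((typed == 2).mean())
                fh = float((typed == 1).mean())
                # ties and monomorphic loci resolve to the lexicographic hom
                major = hom1 if (f1 >= f2 or hom2 is None) else hom2
            records.append(
                {
                    "locus": locus,
                    "group": group,
                    "hom1": hom1,
                    "hom2": hom2,
                    "f_hom1": f1,
                    "f_hom2": f2,
                    "f_het": fh,
                    "f_missing": 1.0 - n_typed / n_group,
                    "n_typed": n_typed,
                    "n_group": n_group,
                    "major": major,
                }
            )
    return pd.DataFrame(records).set_index(["locus", "group"])


def _freq_of(row: pd.Series, genotype: str | None) -> float:
    if genotype is None:
        return 0.0
    if genotype == row["hom1"]:
        return row["f_hom1"]
    if genotype == row["hom2"]:
        return row["f_hom2"]
    return 0.0


def screen_loci(
    profile: pd.DataFrame,
    *,
    threshold: float = 0.45,
    contrasts: list[tuple[str, str]],
    mode: str = "major",
    min_typed_fraction: float = 0.5,
) -> ScreenResult:
    """Select loci with opposite major homozygotes diverging by >= threshold.

    ``contrasts`` is a list of (focal, other) group pairs sharing one focal
    group (the cultivated group in the olive analysis).  ``mode='major'``
    evaluates the frequency difference on the focal group's major homozygote
    only; ``mode='both'`` additionally requires the reciprocal difference on
    the other group's major homozygote.  Loci with fewer than
    ``min_typed_fraction`` typed samples in any contrasted group are skipped.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if mode not in ("major", "both"):
        raise ValueError(f"mode must be 'major' or 'both', got {mode!r}")
    focal_groups = {c[0] for c in contrasts}
    if len(focal_groups) != 1:
        raise ValueError("all contrasts must share one focal group")
    focal = focal_groups.pop()
    others = [c[1] for c in contrasts]

    hits: list[ScreenHit] = []
    skipped: list[str] = []
    counts: dict[str, int] = {}
    for locus in profile.index.get_level_values("locus").unique():
        block = profile.loc[locus]
        frow = block.loc[focal]
        needed = [focal] + others
        typed_frac = {
            g: block.loc[g, "n_typed"] / block.loc[g, "n_group"] for g in needed
        }
        if any(typed_frac[g] < min_typed_fraction for g in needed):
            skipped.append(locus)
            continue
        if frow["major"] is None:
            skipped.append(locus)
            continue
        passed: list[str] = []
        diffs: dict[str, float] = {}
        other_major: str | None = None
        for other in others:
            orow = block.loc[other]
            if orow["major"] is None:
                continue
            diff = _freq_of(frow, frow["major"]) - _freq_of(orow, frow["major"])
            diffs[other] = float(diff)
            ok = frow["major"] != orow["major"] and diff >= threshold
            if ok and mode == "both":
                rec = _freq_of(orow, orow["major"]) - _freq_of(frow, orow["major"])
                ok = rec >= threshold
            if ok:
                passed.append(other)
                other_major = orow["major"]
        if not passed:
            continue
        if len(passed) == len(others) and len(others) > 1:
            category = f"{focal}_vs_{CATEGORY_BOTH}"
        else:
            category = f"{focal}_vs_{passed[0]}"
        freqs = {
            g: {
                "hom1": float(block.loc[g, "f_hom1"]),
                "hom2": float(block.loc[g, "f_hom2"]),
                "het": float(block.loc[g, "f_het"]),
            }
            for g in needed
        }
        hits.append(
            ScreenHit(
                locus_id=locus,
                category=category,
                contrasted_genotypes=(frow["major"], other_major or ""),
                frequencies=freqs,
                differences=diffs,
            )
        )
        counts[category] = counts.get(category, 0) + 1
    return ScreenResult(hits=hits, counts=counts, skipped_loci=skipped)
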