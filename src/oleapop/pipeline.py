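"""End-to-end analysis pipeline: load -> concatenate -> filter -> statistics
-> ordination/tree -> divergence screen -> optional SNP-effect annotation.

Every stage is also callable on its own through the library API or the CLI;
this module wires them together behind one validated configuration, writes
all reports into an output directory and records a run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, popgen, ordination, screen as screen_mod, effects as effects_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run."""

    genotype_table: str
    out_dir: str
    transcripts_fasta: str | None = None
    cds_table: str | None = None
    snp_table: str | None = None  # TSV: locus, transcript, position, ref, alt
    annotation_table: str | None = None
    group_map: dict[str, str] = field(default_factory=dict)
    focal_group: str | None = None
    site_coverage: float = 0.95
    apply_site_filter: bool = True
    screen_threshold: float = 0.45
    screen_mode: str = "major"
    ambiguity_policy: str = "expected"
    pi_sites: str = "all"
    distance_method_pcoa: str = "codominant-squared"
    distance_method_tree: str = "p-distance"
    n_permutations: int = 1000
    n_bootstrap: int = 0
    n_pcoa_axes: int = 3
    write_vcf: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.site_coverage <= 1:
            raise ValueError(f"site_coverage must be in (0, 1], got {self.site_coverage}")
        if not 0 < self.screen_threshold <= 1:
            raise ValueError(
                f"screen_threshold must be in (0, 1], got {self.screen_threshold}"
            )
        if self.screen_mode not in ("major", "both"):
            raise ValueError(f"unknown screen_mode {self.screen_mode!r}")
        if self.ambiguity_policy not in popgen.POLICIES:
            raise ValueError(f"unknown ambiguity_policy {self.ambiguity_policy!r}")
        if self.pi_sites not in ("all", "variable"):
            raise ValueError("pi_sites must be 'all' or 'variable'")
        for m in (self.distance_method_pcoa, self.distance_method_tree):
            if m not in ordination.DISTANCE_METHODS:
                raise ValueError(f"unknown distance method {m!r}")
        if self.n_permutations < 1 or self.n_bootstrap < 0:
            raise ValueError("permutation/bootstrap counts out of range")
        if not Path(self.genotype_table).exists():
            raise FileNotFoundError(self.genotype_table)
        for p in (self.transcripts_fasta, self.cds_table, self.snp_table,
                  self.annotation_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _diversity_frame(summaries: dict[str, popgen.DiversitySummary]) -> pd.DataFrame:
    rows = []
    for name, s in summaries.items():
        taj = s.tajima
        rows.append(
            {
                "group": name,
                "n": s.n,
                "L": s.L,
                "S": s.S,
                "k": s.k,
                "Pi": s.pi,
                "Pi_all_sites": s.pi_all_sites,
                "Pi_variable_sites": s.pi_variable_sites,
                "ThetaW": s.theta_w,
                "Var_ThetaW_norec": s.theta_w_var_norec,
                "Var_ThetaW_freerec": s.theta_w_var_freerec,
                "TajimaD": taj.D if taj else np.nan,
                "TajimaD_significance": taj.significance if taj else "undefined",
            }
        )
    return pd.DataFrame(rows)


def _differentiation_frame(
    pairs: dict[tuple[str, str], popgen.PairwiseDifferentiation]
) -> pd.DataFrame:
    rows = []
    for (g1, g2), d in pairs.items():
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "Ks": d.Ks,
                "Kxy": d.Kxy,
                "Gst": d.Gst,
                "Nst": d.Nst,
                "Fst": d.Fst,
                "Dxy": d.Dxy,
                "Da": d.Da,
                "perm_p_Ks": d.perm_p_Ks,
                "perm_p_Kxy": d.perm_p_Kxy,
                "n_permutations": d.n_permutations,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }
    try:
        from importlib.metadata import version

        manifest["versions"] = {
            "oleapop": version("oleapop"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
    except Exception:  # pragma: no cover - metadata unavailable in odd installs
        manifest["versions"] = {}

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **info,
            }
            logger.info("stage %s done (%.2fs)", name, time.perf_counter() - t0)

        return done

    def emit(key, path):
        manifest["outputs"][key] = str(path)

    # -- load --------------------------------------------------------------
    done = stage("load")
    matrix, partition = io.read_genotype_table(config.genotype_table)
    if config.group_map:
        partition = io.PopulationPartition(
            {s: config.group_map.get(g, g) for s, g in partition.labels.items()}
        )
    partition.validate_against(matrix)
    groups = partition.group_names()
    focal = config.focal_group or (
        io.CULTIVAR if io.CULTIVAR in groups else groups[0]
    )
    if focal not in groups:
        raise ValueError(f"focal group {focal!r} not among groups {groups}")
    done(n_samples=matrix.n_samples, n_loci=matrix.n_loci,
         groups={g: len(m) for g, m in partition.groups().items()})

    # -- IUPAC concatenation + site filter ----------------------------------
    done = stage("concat_filter")
    seqs = io.concatenate_iupac(matrix)
    if config.apply_site_filter:
        seqs = io.filter_sites(seqs, config.site_coverage)
    io.write_fasta(seqs, out / "sequences.fasta")
    emit("sequences_fasta", out / "sequences.fasta")
    done(n_sites_retained=seqs.length, n_sites_removed=seqs.n_removed_sites)

    # -- diversity ----------------------------------------------------------
    done = stage("diversity")
    summaries: dict[str, popgen.DiversitySummary] = {
        "overall": popgen.diversity_summary(
            seqs, policy=config.ambiguity_policy, pi_sites=config.pi_sites
        )
    }
    group_seqs = {}
    for g in groups:
        members = partition.groups()[g]
        group_seqs[g] = seqs.take(members)
        summaries[g] = popgen.diversity_summary(
            group_seqs[g], policy=config.ambiguity_policy, pi_sites=config.pi_sites
        )
    div_df = _diversity_frame(summaries)
    div_df.to_csv(out / "diversity.tsv", sep="\t", index=False)
    emit("diversity_tsv", out / "diversity.tsv")
    done(S_overall=int(summaries["overall"].S))

    # -- differentiation -----------------------------------------------------
    done = stage("differentiation")
    pairs: dict[tuple[str, str], popgen.PairwiseDifferentiation] = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            pairs[(g1, g2)] = popgen.pairwise_differentiation(
                group_seqs[g1],
                group_seqs[g2],
                n_perm=config.n_permutations,
                seed=config.seed,
                policy=config.ambiguity_policy,
            )
    diff_df = _differentiation_frame(pairs)
    diff_df.to_csv(out / "differentiation.tsv", sep="\t", index=False)
    emit("differentiation_tsv", out / "differentiation.tsv")
    done(n_pairs=len(pairs))

    # -- heterozygosity panel ------------------------------------------------
    done = stage("hetstats")
    het = popgen.het_summary(matrix, partition)
    het.summary.to_csv(out / "hetstats.tsv", sep="\t")
    emit("hetstats_tsv", out / "hetstats.tsv")
    done()

    # -- ordination -----------------------------------------------------------
    done = stage("pcoa")
    dist = ordination.genetic_distance(
        matrix, config.distance_method_pcoa, policy=config.ambiguity_policy
    )
    pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids).to_csv(
        out / "distances.tsv", sep="\t"
    )
    emit("distances_tsv", out / "distances.tsv")
    pc = ordination.pcoa(dist, n_axes=config.n_pcoa_axes)
    coords = pd.DataFrame(
        pc.coordinates,
        index=pc.sample_ids,
        columns=[f"axis{i + 1}" for i in range(pc.coordinates.shape[1])],
    )
    coords.insert(0, "group", [partition.group_of(s) for s in pc.sample_ids])
    coords.index.name = "sample"
    coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    eig = pd.DataFrame(
        {"eigenvalue": pc.eigenvalues, "percent_variability": pc.percent}
    )
    eig.index = [f"axis{i + 1}" for i in range(len(pc.eigenvalues))]
    eig.to_csv(out / "pcoa_eigenvalues.tsv", sep="\t")
    emit("pcoa_coordinates_tsv", out / "pcoa_coordinates.tsv")
    emit("pcoa_eigenvalues_tsv", out / "pcoa_eigenvalues.tsv")
    done(percent_axis1=float(pc.percent[0]) if pc.percent.size else 0.0)

    # -- tree -----------------------------------------------------------------
    done = stage("tree")
    if config.n_bootstrap > 0:
        tree, support = ordination.nj_bootstrap(
            matrix,
            method=config.distance_method_tree,
            policy=config.ambiguity_policy,
            n_boot=config.n_bootstrap,
            seed=config.seed + 1,
        )
    else:
        tree_dist = ordination.genetic_distance(
            matrix, config.distance_method_tree, policy=config.ambiguity_policy
        )
        tree = ordination.neighbor_joining(tree_dist)
    io.write_newick(tree.newick(), out / "tree.nwk")
    emit("tree_newick", out / "tree.nwk")
    done(total_branch_length=tree.total_length)

    # -- divergence screen -----------------------------------------------------
    done = stage("screen")
    profile = screen_mod.homozygote_profile(matrix, partition)
    contrasts = [(focal, g) for g in groups if g != focal]
    result = screen_mod.screen_loci(
        profile,
        threshold=config.screen_threshold,
        contrasts=contrasts,
        mode=config.screen_mode,
    )
    hits_df = result.to_frame()
    hits_df.to_csv(out / "screen_hits.tsv", sep="\t", index=False)
    summary = {
        "n_hits": len(result.hits),
        "counts": result.counts,
        "n_skipped_loci": len(result.skipped_loci),
        "threshold": config.screen_threshold,
        "mode": config.screen_mode,
    }
    with open(out / "screen_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    emit("screen_hits_tsv", out / "screen_hits.tsv")
    emit("screen_summary_json", out / "screen_summary.json")
    done(**summary)

    # -- SNP effects (optional) -------------------------------------------------
    if config.transcripts_fasta and config.cds_table and config.snp_table:
        done = stage("effects")
        transcripts = effects_mod.read_transcripts(
            config.transcripts_fasta, config.cds_table
        )
        snp_df = pd.read_csv(config.snp_table, sep="\t", dtype={"transcript": str})
        classified = [
            effects_mod.classify_snp(
                transcripts[str(r["transcript"])],
                int(r["position"]),
                str(r["ref"]),
                str(r["alt"]),
            )
            for _, r in snp_df.iterrows()
        ]
        eff_df = effects_mod.effects_frame(classified)
        if "locus" in snp_df.columns:
            eff_df.insert(0, "locus", snp_df["locus"].to_numpy())
            if not hits_df.empty:
                eff_df = eff_df.merge(
                    hits_df[["locus", "category"]], on="locus", how="left"
                )
        if config.annotation_table and "locus" in eff_df.columns:
            annot = effects_mod.load_annotation(config.annotation_table)
            eff_df = effects_mod.join_annotation(eff_df, annot)
        eff_df.to_csv(out / "snp_effects.tsv", sep="\t", index=False)
        emit("snp_effects_tsv", out / "snp_effects.tsv")
        done(**effects_mod.tally_effects(classified))
    else:
        manifest["stages"]["effects"] = {"skipped": "no transcript inputs"}

    if config.write_vcf:
        io.write_vcf(matrix, out / "genotypes.vcf")
        emit("genotypes_vcf", out / "genotypes.vcf")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    emit_path = out / "manifest.json"
    logger.info("pipeline complete; manifest at %s", emit_path)
    return manifest
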