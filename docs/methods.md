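# Methods

## Data model

The unit of analysis is a biallelic EST–SNP panel: a samples × loci matrix
of unordered diploid nucleotide calls with missing data allowed, plus one
population label per sample (canonically CULTIVAR, WILD, GUANCHICA;
arbitrary labels work). Heterozygotes are stored unordered because phase is
unknown for EST-derived markers and irrelevant to every statistic computed
here. Loci showing more than two alleles are rejected at load with the
offending locus named.

For sequence-style statistics each sample is collapsed into one IUPAC
pseudo-sequence: homozygote → base, heterozygote → two-base ambiguity code,
missing → N. Sites with less than 95% non-N coverage are removed before
tree and diversity computation (the threshold is configurable and the
filter can be disabled; the boundary is inclusive, coverage = 95% is kept).

## Ambiguity policy

Diversity statistics on IUPAC sequences need a difference measure between
ambiguity characters. Two selectable policies:

* **expected** (default): the difference between two characters is the
  probability that two alleles, one drawn uniformly from each character's
  base set, differ (A–R = 0.5, R–R = 0.5, R–Y = 1). Under Hardy–Weinberg
  equilibrium this makes the mean pairwise difference an unbiased estimator
  of the allele-level mismatch probability, and it is defined for every
  character pair.
* **set-disjoint**: 1 when the two base sets are disjoint, else 0 — the
  conservative convention of treating ambiguity codes as compatible unless
  provably different.

Missing characters are handled by pairwise deletion everywhere: a site
enters a pair's difference only when both sequences are non-N, and per-pair
sums are not rescaled to the full length.

## Diversity panel

Per group: segregating sites S (sites with ≥ 2 distinct non-N character
states), mean pairwise differences k, nucleotide diversity π = k/L, and
Watterson's θ_W = S/a₁ with a₁ = Σ_{i<n} 1/i. Two variance estimates
accompany θ_W: Var = θ/a₁ + a₂θ²/a₁² assuming no recombination and
Var = θ/a₁ assuming free recombination.

π admits two normalisation lengths — all retained sites or variable sites
only. Both are always reported (`pi_all_sites`, `pi_variable_sites`) and
the `pi_sites` option selects which one populates the headline `pi` field
(default: all sites). For a pure SNP panel every site is a discovered
variant, so the two coincide once monomorphic-in-sample columns are absent;
they differ when loci are monomorphic within a group, and reporting both
makes the normalisation explicit rather than implicit.

Tajima's D is computed from (n, S, k) with the standard constants
(a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) and D = (k − S/a₁)/√(e₁S + e₂S(S−1)).
D is reported absent when S = 0 and requires n ≥ 4. Significance uses the
beta-distribution approximation: D is assumed to follow a scaled beta on
[a, b] with a = (2/n − 1/a₁)/√e₂, b = ((n+1)/(2n) − 1/a₁)/√e₂ and shapes
fixed by mean 0, variance 1; two-sided 5% and 1% bands are evaluated from
the beta CDF for the exact n rather than interpolated from a printed table.
The result is a category (ns, p<0.05, p<0.01), not a numeric p-value — the
approximation is not accurate enough in the extreme tails to warrant more.

## Differentiation panel

For a pair of groups X, Y of sizes n_X, n_Y over L analysed sites:

* K_xy — mean pairwise difference across groups; D_xy = K_xy/L;
* K_s — sample-size-weighted mean of the within-group k values,
  (n_X k_X + n_Y k_Y)/(n_X + n_Y);
* D_a = D_xy − (π_X + π_Y)/2 (net divergence);
* F_st = 1 − H_w/H_b with H_w the sample-size-weighted mean within-group
  per-site diversity and H_b = D_xy;
* N_st = 1 − k_S/k_T, where k_S weights the within-group k values by pair
  counts n(n−1)/2 (variance weighting) and k_T is the mean pairwise
  difference of the pooled sample;
* G_st — Nei's (H_t − H_s)/H_t on per-site character-state frequencies,
  with H_s the unweighted mean of the two group heterozygosities and H_t
  from mean frequencies, averaged over sites with H_t > 0 and clipped to
  [0, 1].

Note that D_xy averages over *all* cross pairs, so for two samples of the
same population D_a sits slightly below zero (exactly −k/(nL) when one set
is duplicated); this finite-size offset is standard and is asserted, not
hidden, in the tests.

The PM (permutation) test reshuffles the group labels n_perm times
(default 1000, seeded generator) and recomputes K_s and K_xy from the
cached pairwise-difference matrix. Differentiation *raises* K_xy and
*lowers* K_s, so the K_xy p-value is upper-tailed and the K_s p-value
lower-tailed, both with the add-one estimator p = (#extreme + 1)/(n_perm + 1)
so that p = 0 is impossible. Under exchangeable labels both tests are
calibrated (rejection rate ≈ α; verified at α = 0.05 over 500 replicates).

## Heterozygosity panel

Per locus and group, from typed calls only: N (typed samples), Na (observed
alleles), Ne = 1/Σp² (effective alleles), Ho (heterozygote fraction),
He = 1 − Σp², UHe = 2N/(2N−1) · He, F = (He − Ho)/He. F is undefined at
monomorphic loci and excluded from the mean. Summaries are mean ± SE
(SE = sd/√n over defined per-locus values) per group, plus a Total block
pooling all group × locus cells — which is why the Total N is the mean
typed count across groups, not the panel size.

## Distances, PCoA, neighbor joining

The ordination default is the codominant genotypic squared distance for
biallelic loci: per locus 0 for identical genotypes, 1 when one allele is
shared (AA–AB, AB–BB), 4 for opposite homozygotes — equivalently the
squared allele-dosage difference. Per-pair sums are rescaled by
(total loci)/(co-typed loci); a pair with no co-typed loci is an error
naming the pair. Sequence distances (p-distance, Kimura two-parameter) are
computed on the IUPAC sequences under the ambiguity policy, with the K2P
transition/transversion split taken from the expected transition component
of each character pair.

PCoA applies Gower double-centering to −½D², takes the symmetric
eigendecomposition, orders axes by decreasing eigenvalue and scales
eigenvectors by √λ. Per-axis percentages are computed over positive
eigenvalues only; negative eigenvalues (non-Euclidean residue) are reported
separately, never folded into the denominator.

Neighbor joining is the Saitou–Nei agglomeration on the standard Q
criterion; ties break toward the lowest index pair, making the output
deterministic and order-stable. Negative branch-length estimates are
clamped to zero with the deficit moved to the sibling branch (the two-point
sum is preserved). On additive matrices the algorithm recovers the
generating topology and branch lengths exactly. Bootstrap support is
computed by resampling loci with replacement (seeded), rebuilding the tree,
and scoring each internal bipartition of the reference topology by the
fraction of replicates containing it. The Kimura two-parameter and
p-distance options serve tree building; a composite-likelihood distance is
deliberately out of scope, so published total branch lengths computed with
it are not comparable to ours.

## Opposite-homozygosity divergence screen

Each diploid call is merged into one of three haploid-style states: the two
homozygotes (ordered lexicographically per locus) and the heterozygote,
with frequencies computed over typed samples per group — heterozygotes stay
in the denominator as a third state rather than being discarded. The
predominant ("major") homozygote is the argmax of the two homozygote
frequencies, lexicographic on ties.

A locus passes the contrast (focal, other) iff the two groups' major
homozygotes differ **and** f_focal(major_focal) − f_other(major_focal) ≥
threshold (default 0.45, inclusive). Evaluating the difference on the focal
group's major homozygote alone is the weakest condition consistent with the
worked yes/no rule; a stricter mode (`mode="both"`) additionally requires
the reciprocal difference on the other group's major homozygote. Hits
passing both wild contrasts are classified `<focal>_vs_BOTH`, otherwise by
the single passing contrast. Loci with under 50% typed samples in any
contrasted group are skipped and reported. The screen is anti-monotone in
the threshold and invariant to sample order and allele relabeling.

No multiple-testing correction is applied — the procedure is a fixed
frequency-contrast rule, not a hypothesis test.

## SNP effect classification

Transcripts are sense-strand mRNA contigs with 1-based inclusive CDS bounds
(length divisible by 3). A SNP before/after the CDS is UTR5/UTR3; inside
the CDS the containing codon is translated for both alleles with the
standard genetic code (nuclear ESTs; no organellar tables): same residue →
sSNP, else nsSNP, with stop gain/loss flagged. Reference-allele mismatches
against the transcript are errors citing the position and observed base.
Homology search and GO statistics are out of scope; a pre-made annotation
table (locus → gene, GO terms) can be joined onto screen hits instead.

## Synthetic data generator

The generator emulates the analysis' target structure: three populations
(defaults 171/73/16 samples), 1040 biallelic loci, population-specific
drift, planted divergent loci, optional admixture, sporadic missingness.

* **Drift.** Non-planted loci draw an ancestral frequency
  p₀ ~ Uniform(0.05, 0.95) and per-group frequencies from the
  Balding–Nichols beta, p_g ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F); genotypes are
  binomial under HWE. Defaults F = (0.02, 0.03, 0.05) for
  cultivar/wild/guanchica: the cultivated pool is large and admixed (lowest
  drift), the island endemic smallest (highest). The magnitudes are
  order-of-magnitude choices fixed by a design-time model calculation: they
  are the largest round values at which the model-implied rate of
  drift-induced false positives in the 45% screen stays below 1% of loci
  for these group sizes, which is the regime the screen is meant to operate
  in. Larger per-group drift (≥ 0.1) makes the 16-sample group alone
  produce several percent spurious opposite-homozygote contrasts.
* **Planted loci.** Default 124 loci at delta = 0.75, split 72/24/28 across
  the three categories (largest-remainder rounding). The focal group gets
  allele frequency (1+δ)/2 and each contrasted group (1−δ)/2, so the
  homozygote-frequency contrast is δ under HWE; the non-contrasted group in
  single-contrast categories matches the focal frequency so it cannot pass
  its contrast. Planted genotypes are drawn with quasi-exact Hardy–Weinberg
  composition — expected genotype counts n·(p², 2pq, q²) rounded by largest
  remainder and randomly permuted over samples — so the realised contrast is
  within O(1/n) of δ. This is a planting-fidelity choice: with plain
  binomial sampling the realised contrast fluctuates with sd ≈ 0.05–0.08 at
  these group sizes, and a locus "planted at δ = 0.40" would cross the 0.45
  screen threshold in a sizeable fraction of draws, making planted truth
  useless as ground truth near the threshold. Non-planted loci keep honest
  binomial sampling.
* **Admixture** (off by default): a chosen fraction of samples draws each
  allele from a 50/50 mixture of two groups' frequencies while keeping its
  original label — the simplest testable stand-in for ferals and
  introgressed cultivars.
* **Missingness** is i.i.d. per call at rate 0.02 by default; no
  locus- or sample-structured dropout is modelled.
* All randomness flows from the single config seed through one generator;
  identical configs are byte-identical.

What passing tests on this generator do *not* show: the generator has no
linkage between loci, no ascertainment bias in the SNP panel, no
geographically structured admixture and no genotyping-error model, so
screen false-positive rates and PM-test calibration measured here transfer
to real panels only to the extent those features are negligible.

Toy transcripts for effect-classification tests are random sequences with
random in-frame CDS bounds; each carries one SNP whose class is known by
construction (synonymous variants from four-fold degenerate codon families,
non-synonymous from fixed residue-changing codon pairs, UTR variants
outside the CDS).

## Numerical and interface choices

* Pairwise difference matrices are computed once per sequence set (an
  einsum over per-character base-probability vectors) and reused by the
  permutation test, which only re-aggregates group means — this is what
  makes 1000 permutations on 244 samples take seconds.
* Permutation p-values, bootstrap resampling and the generator all use
  `numpy.random.default_rng` seeded explicitly; no global RNG state.
* VCF export places the unanchored EST markers on one synthetic contig at
  1-based consecutive positions, REF = lexicographically smaller allele.
* The differentiation report deliberately omits the two tool-internal
  sequence-differentiation variants sometimes printed alongside N_st and
  F_st by desktop software, as they have no public operational definition.
* Problem sizes in the test suite are scaled to what the statistics need:
  oracle equivalence runs on 200 random panels of ≤ 12 samples × ≤ 30 loci
  (where brute force is exact and fast), calibration on 500 replicates of a
  20-sample panel with 200 permutations, and one full 260 × 1040 pipeline
  run exercises the end-to-end surface.

## Known limitations

* The ambiguity policy changes k and every statistic downstream of it;
  results from desktop tools that silently adopt one convention are
  comparable only under the matching policy.
* N_st follows the variance-weighting idea of the original estimator but is
  not a line-by-line reimplementation of any particular program's variant.
* The Tajima significance band is the beta approximation — adequate for the
  ns / p<0.05 / p<0.01 banding it reports, not for precise tail p-values.
* The screen has no error model: with very small groups (≈ 16 samples),
  sampling noise alone can produce occasional ≥ 45% contrasts at strongly
  drifted loci; the reported per-group frequencies let users audit each hit.
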