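"""Sequence-style diversity and differentiation statistics on IUPAC sequences.

Each sample's concatenated SNP calls form one IUPAC-coded pseudo-sequence in
which an ambiguity character encodes a heterozygous genotype.  The difference
between two characters at a site is defined by a selectable ambiguity policy:

``expected``
    The probability that two alleles, one drawn uniformly from each
    character's base set, differ (A vs R = 0.5, R vs R = 0.5, R vs Y = 1).
    Unbiased under Hardy-Weinberg equilibrium and defined for every pair.
``set-disjoint``
    1 when the two base sets share no base, else 0 — the conservative
    treatment of ambiguity codes as compatible unless provably different.

Missing data (N) is handled by pairwise deletion throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .io import IUPAC_SETS, IUPACSequenceSet, NUCLEOTIDES

POLICIES = ("expected", "set-disjoint")

_N = ord("N")


def _base_prob_table() -> np.ndarray:
    """(256, 4) table: uniform base probabilities for each IUPAC character."""
    tab = np.zeros((256, 4))
    for char, bases in IUPAC_SETS.items():
        row = np.zeros(4)
        for b in bases:
            row[NUCLEOTIDES.index(b)] = 1.0 / len(bases)
        tab[ord(char)] = row
    return tab


def _base_member_table() -> np.ndarray:
    tab = np.zeros((256, 4), dtype=bool)
    for char, bases in IUPAC_SETS.items():
        for b in bases:
            tab[ord(char), NUCLEOTIDES.index(b)] = True
    return tab


_PROB = _base_prob_table()
_MEMBER = _base_member_table()
_VALID = _PROB.sum(axis=1) > 0

# character-pair difference tables, indexed by ASCII code
_DIFF_EXPECTED = np.where(
    np.outer(_VALID, _VALID), 1.0 - _PROB @ _PROB.T, np.nan
)
_DIFF_DISJOINT = np.where(
    np.outer(_VALID, _VALID),
    (_MEMBER.astype(float) @ _MEMBER.T.astype(float)) == 0,
    np.nan,
).astype(float)

# transition component of the expected difference (A<->G, C<->T), for K2P
_TS = np.zeros((256, 256))
for _i, _j in [(0, 2), (2, 0), (1, 3), (3, 1)]:  # A-G, C-T base pairs
    _TS += np.outer(_PROB[:, _i], _PROB[:, _j])
_DIFF_TS = np.where(np.outer(_VALID, _VALID), _TS, np.nan)


def diff_table(policy: str = "expected") -> np.ndarray:
    if policy == "expected":
        return _DIFF_EXPECTED
    if policy == "set-disjoint":
        return _DIFF_DISJOINT
    raise ValueError(f"unknown ambiguity policy {policy!r}; choose from {POLICIES}")


def pairwise_difference_matrix(
    seqs: IUPACSequenceSet, policy: str = "expected"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair summed character differences and co-typed site counts.

    Returns ``(D, C)`` where ``D[i, j]`` is the summed difference over sites
    where neither sequence is N and ``C[i, j]`` the number of such sites.
    """
    codes = seqs.codes
    valid = _VALID[codes]
    C = valid.astype(float) @ valid.T.astype(float)
    if policy == "expected":
        # matmul fast path: sum over sites of (1 - sum_b P1b P2b) restricted
        # to co-valid sites; invalid rows have zero probability mass.
        P = _PROB[codes]  # (n, L, 4)
        match = np.einsum("ilb,jlb->ij", P, P)
        D = C - match
    else:
        table = diff_table(policy)
        n = seqs.n_sequences
        D = np.zeros((n, n))
        for i in range(n):
            row = table[codes[i], codes[i:]]  # (n-i, L)
            D[i, i:] = np.nansum(row, axis=1)
            D[i:, i] = D[i, i:]
        np.fill_diagonal(D, 0.0)
    return D, C


def pairwise_transition_matrix(seqs: IUPACSequenceSet) -> np.ndarray:
    """Per-pair summed expected transition differences (A<->G, C<->T).

    Companion to :func:`pairwise_difference_matrix` under the ``expected``
    policy; the transversion component is the total minus this.
    """
    P = _PROB[seqs.codes]  # (n, L, 4)
    Pswap = P[..., [2, 3, 0, 1]]  # A<->G, C<->T partner probabilities
    return np.einsum("ilb,jlb->ij", P, Pswap)


def segregating_sites(seqs: IUPACSequenceSet) -> int:
    """Number of sites showing >= 2 distinct non-N character states."""
    codes = seqs.codes
    S = 0
    for j in range(seqs.length):
        col = codes[:, j]
        states = np.unique(col[_VALID[col]])
        if states.size >= 2:
            S += 1
    return int(S)


def harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass
class TajimaComponents:
    """All intermediate constants of Tajima's (1989) D statistic."""

    n: int
    S: int
    k: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float
    significance: str  # "ns", "p<0.05", "p<0.01"


def _tajima_beta_params(n: int, a1: float, e2: float) -> tuple[float, float, float, float]:
    """Support [a, b] and shapes of the scaled beta distribution of D.

    D is bounded by the all-singleton and half-frequency configurations;
    assuming mean 0 and variance 1 fixes the two beta shapes.
    """
    se = math.sqrt(e2)
    a = (2.0 / n - 1.0 / a1) / se
    b = ((n + 1.0) / (2.0 * n) - 1.0 / a1) / se
    alpha = -(1.0 + a * b) * b / (b - a)
    bshape = (1.0 + a * b) * a / (b - a)
    return a, b, alpha, bshape


def _tajima_constants(n: int) -> tuple[float, ...]:
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def tajima_significance(D: float, n: int) -> str:
    """Two-sided significance band from the beta-distribution approximation."""
    a1, _, _, _, _, _, _, e2 = _tajima_constants(n)
    a, b, alpha, bshape = _tajima_beta_params(n, a1, e2)
    x = float(np.clip((D - a) / (b - a), 0.0, 1.0))
    cdf = float(beta_dist.cdf(x, bshape, alpha))
    p = 2.0 * min(cdf, 1.0 - cdf)
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def tajima_d(n: int, S: int, k: float) -> TajimaComponents:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs."""
    if n < 4:
        raise ValueError(f"Tajima's D requires n >= 4, got {n}")
    if S < 1:
        raise ValueError("Tajima's D is undefined for S = 0")
    a1, a2, b1, b2, c1, c2, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    D = (k - S / a1) / math.sqrt(var) if var > 0 else 0.0
    return TajimaComponents(
        n=n, S=S, k=k, a1=a1, a2=a2, b1=b1, b2=b2,
        c1=c1, c2=c2, e1=e1, e2=e2, D=D,
        significance=tajima_significance(D, n),
    )


# ---------------------------------------------------------------------------
# within-group diversity


@dataclass
class DiversitySummary:
    """Within-group sequence diversity panel.

    ``pi`` is k normalised by ``pi_length`` (the chosen normalisation length);
    ``pi_all_sites`` and ``pi_variable_sites`` expose both candidate
    normalisations (all analysed sites vs segregating sites only).
    """

    n: int
    L: int
    S: int
    k: float
    pi: float
    pi_length: int
    pi_all_sites: float
    pi_variable_sites: float | None
    theta_w: float
    theta_w_var_norec: float
    theta_w_var_freerec: float
    tajima: TajimaComponents | None


def diversity_summary(
    seqs: IUPACSequenceSet,
    *,
    policy: str = "expected",
    pi_sites: str = "all",
) -> DiversitySummary:
    """S, k, Pi, Watterson's theta and Tajima's D for one group of sequences."""
    n = seqs.n_sequences
    if n < 2:
        raise ValueError("diversity requires >= 2 sequences")
    if pi_sites not in ("all", "variable"):
        raise ValueError("pi_sites must be 'all' or 'variable'")
    L = seqs.length
    D, _ = pairwise_difference_matrix(seqs, policy)
    iu = np.triu_indices(n, 1)
    k = float(D[iu].mean())
    S = segregating_sites(seqs)
    a1 = harmonic(n)
    theta = S / a1
    a2 = harmonic(n, 2)
    var_norec = theta / a1 + a2 * theta * theta / (a1 * a1)
    var_freerec = theta / a1
    pi_all = k / L
    pi_var = k / S if S > 0 else None
    if pi_sites == "variable":
        pi, pi_len = (pi_var if pi_var is not None else 0.0), max(S, 1)
    else:
        pi, pi_len = pi_all, L
    taj = tajima_d(n, S, k) if (S >= 1 and n >= 4) else None
    return DiversitySummary(
        n=n, L=L, S=S, k=k, pi=pi, pi_length=pi_len,
        pi_all_sites=pi_all, pi_variable_sites=pi_var,
        theta_w=theta, theta_w_var_norec=var_norec,
        theta_w_var_freerec=var_freerec, tajima=taj,
    )


# ---------------------------------------------------------------------------
# between-group differentiation


@dataclass
class PairwiseDifferentiation:
    """Between-group differentiation panel for one pair of populations."""

    n_x: int
    n_y: int
    L: int
    Ks: float
    Kxy: float
    Dxy: float
    Da: float
    Fst: float
    Nst: float
    Gst: float
    pi_x: float
    pi_y: float
    perm_p_Ks: float
    perm_p_Kxy: float
    n_permutations: int


def _group_means(D: np.ndarray, ix: np.ndarray, iy: np.ndarray) -> tuple[float, float, float]:
    """Mean pairwise differences within X, within Y and between X and Y."""
    def within(idx):
        if idx.size < 2:
            return 0.0
        sub = D[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, 1)
        return float(sub[iu].mean())

    kx = within(ix)
    ky = within(iy)
    kxy = float(D[np.ix_(ix, iy)].mean())
    return kx, ky, kxy


def _gst_over_sites(codes_x: np.ndarray, codes_y: np.ndarray) -> float:
    """Nei's Gst on per-site character-state frequencies, averaged over sites."""
    vals = []
    for j in range(codes_x.shape[1]):
        colx = codes_x[:, j]
        coly = codes_y[:, j]
        colx = colx[_VALID[colx]]
        coly = coly[_VALID[coly]]
        if colx.size == 0 or coly.size == 0:
            continue
        states = np.unique(np.concatenate([colx, coly]))
        px = np.array([(colx == s).mean() for s in states])
        py = np.array([(coly == s).mean() for s in states])
        hs = 0.5 * ((1 - (px**2).sum()) + (1 - (py**2).sum()))
        pbar = 0.5 * (px + py)
        ht = 1 - (pbar**2).sum()
        if ht > 0:
            vals.append((ht - hs) / ht)
    return float(np.clip(np.mean(vals), 0.0, 1.0)) if vals else 0.0


def pairwise_differentiation(
    seqs_x: IUPACSequenceSet,
    seqs_y: IUPACSequenceSet,
    *,
    n_perm: int = 1000,
    seed: int | None = None,
    policy: str = "expected",
) -> PairwiseDifferentiation:
    """Ks, Kxy, Dxy, Da, Fst, Nst, Gst and permutation p-values for one pair.

    The permutation test reshuffles group labels ``n_perm`` times; the Ks
    p-value is lower-tailed (differentiation depresses within-group
    diversity), the Kxy p-value upper-tailed, both with the +1/+1 estimator.
    """
    nx, ny = seqs_x.n_sequences, seqs_y.n_sequences
    if nx < 2 or ny < 2:
        raise ValueError("each group needs >= 2 sequences")
    if seqs_x.length != seqs_y.length:
        raise ValueError("groups were scored on different site sets")
    L = seqs_x.length
    pooled = IUPACSequenceSet(
        sample_ids=list(seqs_x.sample_ids) + list(seqs_y.sample_ids),
        locus_ids=list(seqs_x.locus_ids),
        codes=np.vstack([seqs_x.codes, seqs_y.codes]),
    )
    D, _ = pairwise_difference_matrix(pooled, policy)
    ix = np.arange(nx)
    iy = np.arange(nx, nx + ny)
    kx, ky, kxy = _group_means(D, ix, iy)

    Ks = (nx * kx + ny * ky) / (nx + ny)
    pi_x, pi_y = kx / L, ky / L
    Dxy = kxy / L
    Da = Dxy - 0.5 * (pi_x + pi_y)
    Hw = (nx * pi_x + ny * pi_y) / (nx + ny)
    Fst = 1.0 - Hw / Dxy if Dxy > 0 else 0.0
    # Nst: pair-count (variance) weighting of within-group diversity against
    # the pooled-sample mean pairwise difference
    cx, cy = nx * (nx - 1) / 2, ny * (ny - 1) / 2
    k_within = (cx * kx + cy * ky) / (cx + cy)
    iu = np.triu_indices(nx + ny, 1)
    k_total = float(D[iu].mean())
    Nst = 1.0 - k_within / k_total if k_total > 0 else 0.0
    Gst = _gst_over_sites(seqs_x.codes, seqs_y.codes)

    rng = np.random.default_rng(seed)
    n_lo = 0
    n_hi = 0
    idx = np.arange(nx + ny)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        pix, piy = perm[:nx], perm[nx:]
        pkx, pky, pkxy = _group_means(D, pix, piy)
        pKs = (nx * pkx + ny * pky) / (nx + ny)
        if pKs <= Ks:
            n_lo += 1
        if pkxy >= kxy:
            n_hi += 1
    p_ks = (n_lo + 1) / (n_perm + 1)
    p_kxy = (n_hi + 1) / (n_perm + 1)

    return PairwiseDifferentiation(
        n_x=nx, n_y=ny, L=L, Ks=Ks, Kxy=kxy, Dxy=Dxy, Da=Da,
        Fst=Fst, Nst=Nst, Gst=Gst, pi_x=pi_x, pi_y=pi_y,
        perm_p_Ks=p_ks, perm_p_Kxy=p_kxy, n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# genotype-level heterozygosity panel


@dataclass
class HetSummary:
    """Per-locus heterozygosity statistics and their mean +/- SE summaries.

    ``per_locus`` has a (group, locus) MultiIndex with columns
    N, Na, Ne, Ho, He, UHe, F; ``summary`` one Mean and SE row per group plus
    a Total block pooling all group x locus cells.
    """

    per_locus: "pd.DataFrame"
    summary: "pd.DataFrame"


def het_summary(matrix, partition) -> HetSummary:
    """Codominant-marker heterozygosity / F-statistics panel per group.

    Allele frequencies come from typed calls only; F = (He - Ho)/He is
    undefined (NaN, excluded from the mean) at monomorphic loci.
    """
    import pandas as pd

    rows = []
    dos = matrix.dosage()
    for group in partition.group_names():
        idx = partition.indices(matrix.sample_ids, group)
        if idx.size == 0:
            raise ValueError(f"group {group!r} has no samples")
        sub = dos[idx]
        for j, locus in enumerate(matrix.locus_ids):
            col = sub[:, j]
            typed = col[~np.isnan(col)]
            N = typed.size
            if N == 0:
                continue  # locus untyped in this group: skipped, logged upstream
            p_alt = typed.sum() / (2 * N)
            p = np.array([1 - p_alt, p_alt])
            na = int((p > 0).sum())
            sum_p2 = float((p**2).sum())
            ne = 1.0 / sum_p2
            ho = float((typed == 1).mean())
            he = 1.0 - sum_p2
            uhe = (2 * N / (2 * N - 1)) * he if N > 1 else np.nan
            f = (he - ho) / he if he > 0 else np.nan
            rows.append((group, locus, N, na, ne, ho, he, uhe, f))
    per_locus = pd.DataFrame(
        rows, columns=["group", "locus", "N", "Na", "Ne", "Ho", "He", "UHe", "F"]
    ).set_index(["group", "locus"])

    def block(df, label):
        mean = df.mean()
        se = df.std(ddof=1) / np.sqrt(df.notna().sum())
        return pd.DataFrame(
            {"stat": ["Mean", "SE"], **{c: [mean[c], se[c]] for c in df.columns}},
            index=pd.Index([label, label], name="group"),
        )

    blocks = [
        block(per_locus.loc[g], g) for g in partition.group_names()
    ]
    blocks.append(block(per_locus.droplevel(0), "Total"))
    summary = pd.concat(blocks)
    return HetSummary(per_locus=per_locus, summary=summary)
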