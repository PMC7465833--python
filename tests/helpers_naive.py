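"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops over dictionaries and
strings, deliberately sharing no code with the package implementation.
"""

from fractions import Fraction

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "M": "AC", "R": "AG", "W": "AT", "S": "CG", "Y": "CT", "K": "GT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}


def char_diff(c1: str, c2: str, policy: str = "expected") -> float:
    """Difference between two IUPAC characters (N handled by the caller)."""
    s1, s2 = IUPAC[c1], IUPAC[c2]
    if policy == "set-disjoint":
        return 0.0 if set(s1) & set(s2) else 1.0
    match = Fraction(0)
    for a in s1:
        for b in s2:
            if a == b:
                match += Fraction(1, len(s1)) * Fraction(1, len(s2))
    return float(1 - match)


def pair_diff(seq1: str, seq2: str, policy: str = "expected") -> tuple[float, int]:
    """Summed difference and co-typed site count for one sequence pair."""
    total, count = 0.0, 0
    for a, b in zip(seq1, seq2):
        if a == "N" or b == "N":
            continue
        total += char_diff(a, b, policy)
        count += 1
    return total, count


def mean_k(seqs: list[str], policy: str = "expected") -> float:
    """Mean pairwise difference over all unordered sequence pairs."""
    total, pairs = 0.0, 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d, _ = pair_diff(seqs[i], seqs[j], policy)
            total += d
            pairs += 1
    return total / pairs


def segregating_sites(seqs: list[str]) -> int:
    S = 0
    for j in range(len(seqs[0])):
        states = {s[j] for s in seqs if s[j] != "N"}
        if len(states) >= 2:
            S += 1
    return S


def watterson_theta(S: int, n: int) -> float:
    return S / sum(1.0 / i for i in range(1, n))


def between_k(x: list[str], y: list[str], policy: str = "expected") -> float:
    total = 0.0
    for sx in x:
        for sy in y:
            d, _ = pair_diff(sx, sy, policy)
            total += d
    return total / (len(x) * len(y))


def differentiation(x: list[str], y: list[str], L: int, policy="expected") -> dict:
    """Ks, Kxy, Dxy, Da, Fst from first principles."""
    nx, ny = len(x), len(y)
    kx = mean_k(x, policy)
    ky = mean_k(y, policy)
    kxy = between_k(x, y, policy)
    ks = (nx * kx + ny * ky) / (nx + ny)
    pix, piy = kx / L, ky / L
    dxy = kxy / L
    da = dxy - (pix + piy) / 2
    hw = (nx * pix + ny * piy) / (nx + ny)
    fst = 1 - hw / dxy if dxy > 0 else 0.0
    return {"Ks": ks, "Kxy": kxy, "Dxy": dxy, "Da": da, "Fst": fst}


def het_stats(calls: list[str]) -> dict:
    """N, Na, Ne, Ho, He, UHe, F for one locus from two-letter call strings."""
    typed = [c for c in calls if c != "NN"]
    N = len(typed)
    alleles: dict[str, int] = {}
    het = 0
    for c in typed:
        if c[0] != c[1]:
            het += 1
        for a in c:
            alleles[a] = alleles.get(a, 0) + 1
    freqs = [v / (2 * N) for v in alleles.values()]
    sum_p2 = sum(p * p for p in freqs)
    ho = het / N
    he = 1 - sum_p2
    uhe = (2 * N / (2 * N - 1)) * he if N > 1 else float("nan")
    f = (he - ho) / he if he > 0 else float("nan")
    return {
        "N": N, "Na": len(alleles), "Ne": 1 / sum_p2,
        "Ho": ho, "He": he, "UHe": uhe, "F": f,
    }


def codominant_sq(calls1: list[str], calls2: list[str]) -> float:
    """Codominant genotypic squared distance (0/1/4 scheme) for one pair."""
    total, typed, loci = 0.0, 0, 0
    for c1, c2 in zip(calls1, calls2):
        loci += 1
        if c1 == "NN" or c2 == "NN":
            continue
        typed += 1
        g1 = tuple(sorted(c1))
        g2 = tuple(sorted(c2))
        if g1 == g2:
            d = 0
        else:
            shared = len(set(c1) & set(c2))
            het1 = g1[0] != g1[1]
            het2 = g2[0] != g2[1]
            if het1 or het2:
                d = 1  # one allele shared between AA and AB, or AB vs AA
            else:
                d = 4 if shared == 0 else 1
        total += d
    return total * loci / typed


#: the standard genetic code, written out by hand (independent of Biopython)
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
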