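import math

import numpy as np
import pytest
import sympy

import oleapop as op
from oleapop.io import IUPACSequenceSet
from oleapop.popgen import (
    diff_table,
    pairwise_difference_matrix,
    segregating_sites,
    tajima_significance,
)
from conftest import random_iupac_seqs
import helpers_naive as naive


def seqset(*seqs):
    return IUPACSequenceSet.from_strings([f"s{i}" for i in range(len(seqs))], list(seqs))


class TestAmbiguityPolicies:
    @pytest.mark.parametrize(
        "c1,c2,expected",
        [ ("A", "A", 0.0), ("A", "G", 1.0), ("A", "R", 0.5),
          ("R", "R", 0.5), ("R", "Y", 1.0), ("R", "K", 0.75) ],
    )
    def test_expected_policy_values(self, c1, c2, expected):
        tab = diff_table("expected")
        assert tab[ord(c1), ord(c2)] == pytest.approx(expected, abs=1e-15)

    def test_set_disjoint_policy(self):
        tab = diff_table("set-disjoint")
        assert tab[ord("A"), ord("R")] == 0.0  # sets overlap
        assert tab[ord("R"), ord("Y")] == 1.0  # disjoint
        assert tab[ord("A"), ord("A")] == 0.0

    @pytest.mark.parametrize("policy", ["expected", "set-disjoint"])
    def test_tables_match_naive_definition(self, policy):
        tab = diff_table(policy)
        for c1 in naive.IUPAC:
            for c2 in naive.IUPAC:
                assert tab[ord(c1), ord(c2)] == pytest.approx(
                    naive.char_diff(c1, c2, policy), abs=1e-15
                )


class TestDiversity:
    def test_two_sequences_three_differences(self):
        s = seqset("AAAAACCCCC", "AAAAACCGGT")
        d = op.diversity_summary(s, pi_sites="all")
        assert d.k == pytest.approx(3.0)
        assert d.S == 3
        assert d.pi == pytest.approx(0.3)
        assert d.theta_w == pytest.approx(3.0)  # a1 = 1 for n = 2

    def test_pi_normalisations_both_reported(self):
        s = seqset("AAAA", "AAAT", "AAAT")
        d = op.diversity_summary(s)
        assert d.pi_all_sites == pytest.approx(d.k / 4)
        assert d.pi_variable_sites == pytest.approx(d.k / d.S)

    @pytest.mark.parametrize("policy", ["expected", "set-disjoint"])
    def test_matches_bruteforce_on_random_sequences(self, rng, policy):
        for _ in range(20):
            s = random_iupac_seqs(rng, n=8, L=40)
            d = op.diversity_summary(s, policy=policy)
            strs = s.sequences()
            assert d.k == pytest.approx(naive.mean_k(strs, policy), abs=1e-12)
            assert d.S == naive.segregating_sites(strs)
            assert d.theta_w == pytest.approx(
                naive.watterson_theta(d.S, 8), abs=1e-12
            )

    def test_pairwise_deletion_of_n_positions(self):
        s = seqset("ANA", "AGA")  # site 2 dropped for this pair
        D, C = pairwise_difference_matrix(s)
        assert C[0, 1] == 2
        assert D[0, 1] == 0.0

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            op.diversity_summary(seqset("ACGT"))


class TestTajima:
    def test_harmonic_example(self):
        comp = op.tajima_d(5, 4, 2.0)
        assert comp.a1 == pytest.approx(25 / 12)
        assert 4 / comp.a1 == pytest.approx(1.92)

    @pytest.mark.parametrize("n,S", [(4, 1), (10, 16), (25, 7), (50, 100)])
    def test_zero_when_k_equals_theta(self, n, S):
        comp = op.tajima_d(n, S, S / op.popgen.harmonic(n))
        assert comp.D == 0.0

    @pytest.mark.parametrize("n", range(4, 51))
    def test_components_match_extended_precision(self, n):
        ns = sympy.Integer(n)
        a1 = sum(sympy.Rational(1, i) for i in range(1, n))
        a2 = sum(sympy.Rational(1, i**2) for i in range(1, n))
        b1 = sympy.Rational(n + 1, 3 * (n - 1))
        b2 = sympy.Rational(2 * (n * n + n + 3), 9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - sympy.Rational(n + 2, n) / a1 + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        S, k = 16, 3.888
        D_exact = (sympy.Float(k, 30) - S / a1) / sympy.sqrt(
            e1 * S + e2 * S * (S - 1)
        )
        comp = op.tajima_d(n, S, k)
        for got, exact in [
            (comp.a1, a1), (comp.a2, a2), (comp.b1, b1), (comp.b2, b2),
            (comp.c1, c1), (comp.c2, c2), (comp.e1, e1), (comp.e2, e2),
            (comp.D, D_exact),
        ]:
            assert got == pytest.approx(float(sympy.N(exact, 30)), rel=1e-12)

    def test_significance_bands(self):
        # strongly positive D in a large sample is flagged, near-zero is not
        assert tajima_significance(3.244, 171) == "p<0.01"
        assert tajima_significance(0.556, 16) == "ns"
        assert tajima_significance(0.0, 30) == "ns"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            op.tajima_d(3, 5, 1.0)
        with pytest.raises(ValueError):
            op.tajima_d(10, 0, 0.0)


class TestDifferentiation:
    def test_fixed_monomorphic_haplotypes(self):
        x = seqset("AAAAA", "AAAAA")
        y = seqset("AAGGG", "AAGGG")
        d = op.pairwise_differentiation(x, y, n_perm=50, seed=0)
        assert d.Dxy == pytest.approx(3 / 5)
        assert d.Da == pytest.approx(3 / 5)
        assert d.Fst == pytest.approx(1.0)

    def test_identical_groups_show_no_differentiation(self, rng):
        # duplicating one set: between-group pairs include each sequence with
        # its own copy, so Kxy = (n-1)/n * k exactly and Da/Fst sit at their
        # known (slightly negative) no-differentiation finite-size values
        n, L = 5, 30
        s = random_iupac_seqs(rng, n=n, L=L, chars="ACGT")
        x = IUPACSequenceSet.from_strings([f"x{i}" for i in range(n)], s.sequences())
        y = IUPACSequenceSet.from_strings([f"y{i}" for i in range(n)], s.sequences())
        d = op.pairwise_differentiation(x, y, n_perm=200, seed=1)
        k_within = op.diversity_summary(x).k
        assert d.Kxy == pytest.approx((n - 1) / n * k_within, abs=1e-12)
        assert d.Da == pytest.approx(-k_within / (n * L), abs=1e-12)
        assert d.Fst == pytest.approx(-1 / (n - 1), abs=1e-12)
        assert d.perm_p_Kxy > 0.05

    def test_exchangeable_groups_not_significant(self, rng):
        pool = random_iupac_seqs(rng, n=24, L=50, chars="ACGT")
        x = pool.take(pool.sample_ids[:12])
        y = pool.take(pool.sample_ids[12:])
        d = op.pairwise_differentiation(x, y, n_perm=300, seed=3)
        assert d.perm_p_Kxy > 0.05
        assert d.perm_p_Ks > 0.05
        assert abs(d.Fst) < 0.1

    def test_matches_bruteforce(self, rng):
        for _ in range(10):
            sx = random_iupac_seqs(rng, n=6, L=30)
            sy = random_iupac_seqs(rng, n=6, L=30)
            d = op.pairwise_differentiation(sx, sy, n_perm=10, seed=0)
            ref = naive.differentiation(sx.sequences(), sy.sequences(), 30)
            for key in ("Ks", "Kxy", "Dxy", "Da", "Fst"):
                assert getattr(d, key) == pytest.approx(ref[key], abs=1e-12)

    def test_symmetry_of_group_symmetric_fields(self, rng):
        sx = random_iupac_seqs(rng, n=5, L=25)
        sy = random_iupac_seqs(rng, n=7, L=25)
        d1 = op.pairwise_differentiation(sx, sy, n_perm=10, seed=0)
        d2 = op.pairwise_differentiation(sy, sx, n_perm=10, seed=0)
        for key in ("Ks", "Kxy", "Dxy", "Da", "Fst", "Nst", "Gst"):
            assert getattr(d1, key) == pytest.approx(getattr(d2, key), abs=1e-12)

    def test_permutation_pvalues_reproducible_and_consistent(self, rng):
        sx = random_iupac_seqs(rng, n=6, L=30)
        sy = random_iupac_seqs(rng, n=6, L=30)
        d1 = op.pairwise_differentiation(sx, sy, n_perm=300, seed=7)
        d2 = op.pairwise_differentiation(sx, sy, n_perm=300, seed=7)
        assert d1.perm_p_Kxy == d2.perm_p_Kxy
        d3 = op.pairwise_differentiation(sx, sy, n_perm=300, seed=8)
        # another seed agrees within binomial error on the permutation null
        se = 3 * math.sqrt(0.25 / 300)
        assert abs(d1.perm_p_Kxy - d3.perm_p_Kxy) < se

    def test_differentiation_monotone_in_planted_divergence(self):
        fst, da = [], []
        for delta in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = op.SimulationConfig(
                group_sizes=(40, 30, 10), n_loci=200, n_planted=40,
                planted_delta=delta, missing_rate=0.0, seed=6,
            )
            mat, part, _ = op.simulate_genotypes(cfg)
            seqs = op.concatenate_iupac(mat)
            d = op.pairwise_differentiation(
                seqs.take(part.groups()["CULTIVAR"]),
                seqs.take(part.groups()["WILD"]),
                n_perm=5, seed=0,
            )
            fst.append(d.Fst)
            da.append(d.Da)
        assert all(b >= a - 1e-12 for a, b in zip(fst, fst[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(da, da[1:]))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            op.pairwise_differentiation(seqset("AA"), seqset("AA", "AT"))


class TestHetSummary:
    def _matrix_from_calls(self, calls, labels):
        from oleapop.io import _CODE, MISSING

        n, m = len(calls), len(calls[0])
        a1 = np.full((n, m), MISSING, dtype=np.int8)
        a2 = np.full((n, m), MISSING, dtype=np.int8)
        for i, row in enumerate(calls):
            for j, c in enumerate(row):
                if c != "NN":
                    x, y = sorted(_CODE[ch] for ch in c)
                    a1[i, j], a2[i, j] = x, y
        ids = [f"s{i}" for i in range(n)]
        mat = op.GenotypeMatrix(ids, [f"l{j}" for j in range(m)], a1, a2)
        part = op.PopulationPartition(dict(zip(ids, labels)))
        return mat, part

    def test_all_heterozygous_locus(self):
        mat, part = self._matrix_from_calls([["AG"], ["AG"], ["AG"]], ["P"] * 3)
        row = op.het_summary(mat, part).per_locus.loc[("P", "l0")]
        assert row["Ho"] == 1.0
        assert row["He"] == pytest.approx(0.5)
        assert row["F"] == pytest.approx(-1.0)

    def test_monomorphic_locus(self):
        mat, part = self._matrix_from_calls([["AA"], ["AA"]], ["P"] * 2)
        row = op.het_summary(mat, part).per_locus.loc[("P", "l0")]
        assert row["Na"] == 1
        assert row["Ne"] == 1.0
        assert row["Ho"] == row["He"] == 0.0
        assert np.isnan(row["F"])

    def test_unbiased_he_factor_at_two_samples(self):
        mat, part = self._matrix_from_calls([["AA"], ["AG"]], ["P"] * 2)
        row = op.het_summary(mat, part).per_locus.loc[("P", "l0")]
        assert row["UHe"] == pytest.approx(row["He"] * 4 / 3)

    def test_matches_bruteforce_counting(self, rng):
        from conftest import random_matrix

        mat = random_matrix(rng, n_samples=10, n_loci=12, missing_rate=0.15)
        part = op.PopulationPartition({s: "P" for s in mat.sample_ids})
        got = op.het_summary(mat, part).per_locus
        calls = mat.calls_str()
        for j, locus in enumerate(mat.locus_ids):
            expected = naive.het_stats(list(calls[:, j]))
            if expected["N"] == 0:
                assert ("P", locus) not in got.index
                continue
            row = got.loc[("P", locus)]
            for key in ("N", "Na", "Ne", "Ho", "He", "UHe"):
                assert row[key] == pytest.approx(expected[key], abs=1e-12)
            if math.isnan(expected["F"]):
                assert np.isnan(row["F"])
            else:
                assert row["F"] == pytest.approx(expected["F"], abs=1e-12)
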