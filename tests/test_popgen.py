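"""Frequencies, HWE, Weir–Cockerham Fst, exact tests, Fisher's method, MDS."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import chi2, fisher_exact, hypergeom

from breedauth import (
    AlleleFrequencyTable,
    Genotype,
    GenotypeCountTable,
    MC1R,
    MarkovChainConfig,
    NR6A1,
    ValidationError,
    allele_frequencies,
    classical_mds,
    combine_pvalues_fisher,
    differentiation_pair,
    exact_g_test,
    genotype_frequencies,
    hwe_test,
    wc_fst_pair,
)
from conftest import random_count_table, wc_theta_anova


class TestFrequencies:
    def test_table1_allele_frequencies_exact(self, table1_sample):
        counts = table1_sample.genotype_counts()
        freqs = allele_frequencies(counts, MC1R)
        assert freqs["e"] == Fraction(564, 714)
        assert float(freqs["e"]) == pytest.approx(0.790, abs=5e-4)
        assert allele_frequencies(counts, NR6A1)["C"] == Fraction(3, 714)

    def test_table1_genotype_frequencies(self, table1_sample):
        counts = table1_sample.genotype_counts()
        gf = genotype_frequencies(counts, MC1R)
        assert gf[Genotype(MC1R, "e", "e")] == Fraction(225, 357)
        assert float(gf[Genotype(MC1R, "e", "e")]) == pytest.approx(0.630, abs=5e-4)
        nf = genotype_frequencies(counts, NR6A1)
        assert float(nf[Genotype(NR6A1, "T", "T")]) == pytest.approx(0.994, abs=5e-4)

    def test_single_animal_is_fixed(self):
        t = GenotypeCountTable.from_genotype_counts("x", {"MC1R": {"e/e": 1}})
        assert allele_frequencies(t, "MC1R")["e"] == 1

    def test_all_same_genotype_frequency_one(self):
        t = GenotypeCountTable.from_genotype_counts("x", {"MC1R": {"E+/e": 7}})
        assert genotype_frequencies(t, "MC1R")[Genotype(MC1R, "E+", "e")] == 1

    def test_zero_animals_is_an_error(self):
        t = GenotypeCountTable.from_genotype_counts("x", {"MC1R": {}})
        with pytest.raises(ValidationError):
            allele_frequencies(t, "MC1R")


class TestHWE:
    def test_perfect_hwe_counts_give_statistic_zero(self):
        t = GenotypeCountTable.from_genotype_counts(
            "x", {"NR6A1": {"T/T": 25, "T/C": 50, "C/C": 25}}
        )
        res = hwe_test(t, "NR6A1")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_monomorphic_locus_is_degenerate_p_one(self):
        t = GenotypeCountTable.from_genotype_counts("x", {"NR6A1": {"T/T": 50}})
        for method in ("chi_square", "exact"):
            res = hwe_test(t, "NR6A1", method=method)
            assert res.degenerate and res.p_value == 1.0

    def test_retained_sample_chi_square_matches_hand_computation(self, retained_counts):
        res = hwe_test(retained_counts, "MC1R")
        # Pearson statistic from expected counts n*p^2, 2npq, n*q^2
        n, pe = 342, 553 / 684
        exp = [n * pe * pe, 2 * n * pe * (1 - pe), n * (1 - pe) ** 2]
        stat = sum((o - e) ** 2 / e for o, e in zip([222, 109, 11], exp))
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.p_value == pytest.approx(float(chi2.sf(stat, 1)), rel=1e-12)

    def test_retained_sample_exact_p_matches_permutation_verified_value(
        self, retained_counts
    ):
        # frozen from an independent 20k-permutation oracle (0.7288 +/- 0.003)
        res = hwe_test(retained_counts, "MC1R", method="exact")
        assert res.p_value == pytest.approx(0.7269747859093104, rel=1e-9)

    def test_exact_probabilities_sum_to_one_over_support(self):
        # internal consistency of the conditional distribution on a small case
        t = GenotypeCountTable.from_genotype_counts(
            "x", {"NR6A1": {"T/T": 6, "T/C": 5, "C/C": 2}}
        )
        res = hwe_test(t, "NR6A1", method="exact")
        assert 0.0 < res.p_value <= 1.0

    def test_exact_matches_brute_force_enumeration_small(self):
        # n=13, allele counts 17/9: enumerate heterozygote counts directly
        t = GenotypeCountTable.from_genotype_counts(
            "x", {"NR6A1": {"T/T": 6, "T/C": 5, "C/C": 2}}
        )
        n, na, nb, obs = 13, 17, 9, 5
        probs = {}
        for h in range(na % 2, min(na, nb) + 1, 2):
            naa, nbb = (na - h) // 2, (nb - h) // 2
            probs[h] = (
                math.factorial(n) / (math.factorial(naa) * math.factorial(h)
                                     * math.factorial(nbb))
                * 2**h
                * math.factorial(na) * math.factorial(nb)
                / math.factorial(2 * n)
            )
        expected = sum(p for p in probs.values() if p <= probs[obs] * (1 + 1e-9))
        res = hwe_test(t, "NR6A1", method="exact")
        assert res.p_value == pytest.approx(expected, rel=1e-9)


class TestWeirCockerham:
    def test_identical_samples_theta_near_zero(self, retained_counts):
        res = wc_fst_pair(retained_counts, retained_counts)
        assert abs(res.multi_locus_theta) < 0.01

    def test_theta_symmetric_in_population_order(self, retained_counts, duroc_counts):
        ab = wc_fst_pair(retained_counts, duroc_counts).multi_locus_theta
        ba = wc_fst_pair(duroc_counts, retained_counts).multi_locus_theta
        assert ab == pytest.approx(ba, abs=1e-14)

    def test_monomorphic_locus_contributes_nothing(self, retained_counts, duroc_counts):
        res = wc_fst_pair(retained_counts, duroc_counts)
        # NR6A1 fixed for T in both populations
        assert res.per_locus_theta["NR6A1"] is None
        only_mc1r = wc_fst_pair(retained_counts, duroc_counts, ["MC1R"])
        assert res.multi_locus_theta == pytest.approx(only_mc1r.multi_locus_theta)

    def test_no_informative_locus_is_undefined(self, duroc_counts):
        with pytest.raises(ValidationError):
            wc_fst_pair(duroc_counts, duroc_counts)

    @pytest.mark.parametrize("seed", [1, 7, 42, 1234])
    def test_agrees_with_independent_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_count_table(
            rng, "A",
            {"MC1R": ("E+", "ED2", "e"), "NR6A1": ("C", "T")},
            int(rng.integers(10, 60)),
        )
        b = random_count_table(
            rng, "B",
            {"MC1R": ("E+", "ED2", "e"), "NR6A1": ("C", "T")},
            int(rng.integers(10, 60)),
        )
        theta = wc_fst_pair(a, b).multi_locus_theta
        assert theta == pytest.approx(wc_theta_anova([a, b]), abs=1e-10)

    def test_null_distribution_unbiased(self):
        # two samples from the same frequencies: mean theta within [-0.02, 0.02]
        rng = np.random.default_rng(2024)
        p = np.array([0.64, 0.32, 0.04])  # HWE genotype probs for p(A)=0.8
        thetas = []
        for _ in range(200):
            tables = []
            for name in ("A", "B"):
                naa, nab, nbb = rng.multinomial(200, p)
                tables.append(GenotypeCountTable.from_genotype_counts(
                    name, {"NR6A1": {"T/T": int(naa), "T/C": int(nab),
                                     "C/C": int(nbb)}}
                ))
            try:
                thetas.append(wc_fst_pair(*tables, ["NR6A1"]).multi_locus_theta)
            except ValidationError:
                pass  # (vanishingly rare) double-monomorphic draw
        assert -0.02 < float(np.mean(thetas)) < 0.02


class TestExactGTest:
    def test_identical_counts_give_p_one(self):
        res = exact_g_test({"E+": 20, "e": 80}, {"E+": 20, "e": 80})
        assert res.exact and res.p == pytest.approx(1.0)

    def test_monomorphic_pooled_locus_uninformative(self):
        res = exact_g_test({"T": 100}, {"T": 40})
        assert not res.informative and res.p is None

    @pytest.mark.parametrize("table", [
        ((12, 5), (3, 9)),
        ((1, 19), (4, 16)),
        ((10, 10), (10, 10)),
    ])
    def test_2x2_enumeration_equals_hypergeometric_oracle(self, table):
        (a, b), (c, d) = table
        res = exact_g_test({"A": a, "B": b}, {"A": c, "B": d})
        # oracle: sum hypergeometric pmf over outcomes no more probable
        M, n, N = a + b + c + d, a + c, a + b
        pmf_obs = hypergeom.pmf(a, M, n, N)
        support = range(max(0, N - (b + d)), min(N, n) + 1)
        expected = sum(
            hypergeom.pmf(x, M, n, N)
            for x in support
            if hypergeom.pmf(x, M, n, N) <= pmf_obs * (1 + 1e-9)
        )
        assert res.p == pytest.approx(expected, rel=1e-9)
        assert res.p == pytest.approx(
            fisher_exact([[a, b], [c, d]])[1], rel=1e-7
        )

    def test_2x3_enumeration_probabilities_normalise(self):
        res = exact_g_test({"A": 5, "B": 3, "C": 2}, {"A": 1, "B": 6, "C": 4})
        assert res.exact and 0.0 < res.p <= 1.0
        assert res.n_tables > 1

    def test_mc_agrees_with_enumeration_within_three_se(self):
        a, b = {"A": 14, "B": 26}, {"A": 22, "B": 18}
        enum = exact_g_test(a, b, method="enumeration")
        config = MarkovChainConfig(dememorisation=2000, batches=50,
                                   iterations_per_batch=1000, seed=5)
        mc = exact_g_test(a, b, config=config, method="mc")
        assert abs(mc.p - enum.p) <= 3 * mc.se

    def test_mc_requires_seeded_config(self):
        with pytest.raises(ValidationError):
            exact_g_test({"A": 5, "B": 5}, {"A": 4, "B": 6}, method="mc")

    def test_differentiation_pair_combines_informative_loci_only(
        self, retained_counts, duroc_counts
    ):
        res = differentiation_pair(retained_counts, duroc_counts,
                                   method="enumeration")
        assert not res.g_per_locus["NR6A1"].informative
        assert res.combined_p == pytest.approx(res.g_per_locus["MC1R"].p)


class TestFisherCombination:
    def test_single_p_returned_unchanged(self):
        assert combine_pvalues_fisher([0.5]) == 0.5

    def test_all_ones_stay_one(self):
        assert combine_pvalues_fisher([1.0, 1.0]) == pytest.approx(1.0)

    def test_matches_closed_form(self):
        stat = -2 * (math.log(0.1) + math.log(0.1))
        assert combine_pvalues_fisher([0.1, 0.1]) == pytest.approx(
            float(chi2.sf(stat, 4)), rel=1e-12
        )

    def test_empty_list_undefined(self):
        with pytest.raises(ValidationError):
            combine_pvalues_fisher([])


def _planar_table(points: np.ndarray) -> AlleleFrequencyTable:
    entries = {
        f"P{i}": {"XY": ({"x": float(x), "y": float(y)}, 1)}
        for i, (x, y) in enumerate(points)
    }
    return AlleleFrequencyTable(entries=entries)


class TestClassicalMDS:
    def test_planar_points_recovered_to_1e9(self):
        rng = np.random.default_rng(3)
        pts = rng.random((6, 2))
        res = classical_mds(_planar_table(pts), dims=2)
        coords = np.array([res.coordinates[f"P{i}"] for i in range(6)])
        for i in range(6):
            for j in range(i + 1, 6):
                d = np.linalg.norm(coords[i] - coords[j])
                assert d == pytest.approx(res.distance_matrix[i, j], abs=1e-9)

    def test_two_populations_single_axis_exact_distance(self):
        pts = np.array([[0.1, 0.2], [0.7, 0.9]])
        res = classical_mds(_planar_table(pts), dims=2)
        coords = np.array([res.coordinates["P0"], res.coordinates["P1"]])
        d = np.linalg.norm(coords[0] - coords[1])
        assert d == pytest.approx(float(np.linalg.norm(pts[0] - pts[1])), abs=1e-12)

    def test_identical_frequency_vectors_colocate(self, table2_panel):
        res = classical_mds(table2_panel, dims=2)
        fixed = ["Belgian Landrace", "Italian Large White", "Italian Landrace",
                 "Pietrain"]
        ref = np.array(res.coordinates[fixed[0]])
        for breed in fixed[1:]:
            assert np.allclose(res.coordinates[breed], ref, atol=1e-9)

    def test_full_rank_embedding_reproduces_panel_distances(self, table2_panel):
        n = len(table2_panel.breeds())
        res = classical_mds(table2_panel, dims=n - 1)
        breeds = res.populations
        coords = np.array([res.coordinates[b] for b in breeds])
        diff = coords[:, None, :] - coords[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
        assert np.allclose(D, res.distance_matrix, atol=1e-9)

    def test_truncation_warns_and_reports_inertia(self, table2_panel):
        with pytest.warns(UserWarning):
            res = classical_mds(_planar_table(np.array([[0, 0], [1, 0], [0, 1]])),
                                dims=5)
        assert 0.0 < res.explained_inertia <= 1.0
        res2 = classical_mds(table2_panel, dims=2)
        assert 0.0 < res2.explained_inertia <= 1.0
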