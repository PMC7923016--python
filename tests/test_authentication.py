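"""|delta| differentials, error rates, PMR and the authentication verdict."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from breedauth import (
    Genotype,
    GenotypeCountTable,
    MC1R,
    NR6A1,
    ValidationError,
    assignment_probability,
    authenticate_sample,
    build_summary_table,
    combined_error_rate,
    delta_differential,
    error_rate,
    round_half_up,
)
from breedauth.popgen import genotype_frequencies

MR = {"E+": 0.192, "e": 0.809, "ED1": 0.0, "ED2": 0.0, "EP": 0.0}
APULO = {"E+": 0.040, "e": 0.035, "ED1": 0.0, "ED2": 0.856, "EP": 0.069}
WILD_BOAR = {"E+": 0.925, "e": 0.022, "ED1": 0.0, "ED2": 0.004, "EP": 0.049}
TARGET_ALLELES = ("E+", "e")


class TestDelta:
    def test_combined_against_apulo(self):
        d = delta_differential(MR, APULO, TARGET_ALLELES, "combined")
        assert round_half_up(d.value) == 0.925

    def test_identical_vectors_give_zero(self):
        exact = {"E+": 131 / 684, "e": 553 / 684}
        d = delta_differential(exact, exact, TARGET_ALLELES, "combined")
        assert d.value == pytest.approx(0.0, abs=1e-12)
        # printed 3-decimal vectors drift by rounding: |delta| = 0.001, not 0
        drift = delta_differential(MR, MR, TARGET_ALLELES, "combined")
        assert drift.value == pytest.approx(0.001, abs=1e-9)

    def test_wild_boar_combined_and_per_allele_range(self):
        d = delta_differential(MR, WILD_BOAR, TARGET_ALLELES, "combined")
        assert round_half_up(d.value) == 0.053
        r = delta_differential(MR, WILD_BOAR, TARGET_ALLELES, "per_allele_range")
        lo, hi = r.range
        assert (round_half_up(lo), round_half_up(hi)) == (0.733, 0.787)

    def test_per_allele_average_is_mean_of_components(self):
        d = delta_differential(MR, WILD_BOAR, TARGET_ALLELES, "per_allele_average")
        assert d.value == pytest.approx(
            sum(d.per_allele_values.values()) / 2, rel=1e-12
        )
        assert round_half_up(d.value) == 0.760

    def test_target_not_summing_to_one_is_a_precondition_error(self):
        with pytest.raises(ValidationError):
            delta_differential({"E+": 0.5, "e": 0.3}, APULO, TARGET_ALLELES)


class TestErrorRates:
    def test_apulo_error_rate(self):
        assert round_half_up(error_rate(0.925)) == 0.075

    def test_delta_one_gives_zero_error(self):
        assert error_rate(1.0) == 0.0

    def test_wild_boar_averaged_error_rate(self):
        d = delta_differential(MR, WILD_BOAR, TARGET_ALLELES, "per_allele_average")
        assert round_half_up(error_rate(d)) == 0.240

    def test_combined_error_rate_rounding(self):
        assert round_half_up(combined_error_rate(0.075, 0.856)) == 0.064
        assert round_half_up(combined_error_rate(0.240, 0.018)) == 0.004

    def test_product_with_zero_is_zero(self):
        assert combined_error_rate(0.7, 0.0) == 0.0

    @given(
        d1=st.floats(0, 1, allow_nan=False),
        d2=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_error_rate_identities(self, d1, d2):
        er1, er2 = error_rate(d1), error_rate(d2)
        erc = combined_error_rate(er1, er2)
        assert 0.0 <= erc <= min(er1, er2)  # product rule bound
        assert erc == pytest.approx(er1 * er2)  # exact identity, full precision


class TestAssignmentProbability:
    def test_duroc_all_allowed_genotypes_gives_zero(self, standard):
        duroc = GenotypeCountTable.from_genotype_counts(
            "Italian Duroc", {"MC1R": {"e/e": 30}})
        gf = {g: float(f) for g, f in genotype_frequencies(duroc, "MC1R").items()}
        assert assignment_probability(gf, standard.allowed_genotypes["MC1R"]) == 0.0

    def test_large_white_no_allowed_genotypes_gives_one(self, standard):
        ilw = GenotypeCountTable.from_genotype_counts(
            "Italian Large White", {"MC1R": {"EP/EP": 49}})
        gf = {g: float(f) for g, f in genotype_frequencies(ilw, "MC1R").items()}
        assert assignment_probability(gf, standard.allowed_genotypes["MC1R"]) == 1.0

    def test_population_without_tt_gives_one(self, standard):
        wb = GenotypeCountTable.from_genotype_counts(
            "Wild Boar", {"NR6A1": {"C/C": 100}})
        gf = {g: float(f) for g, f in genotype_frequencies(wb, "NR6A1").items()}
        assert assignment_probability(gf, standard.allowed_genotypes["NR6A1"]) == 1.0

    def test_frequencies_must_sum_to_one(self, standard):
        with pytest.raises(ValidationError):
            assignment_probability(
                {Genotype(MC1R, "e", "e"): 0.5},
                standard.allowed_genotypes["MC1R"],
            )


class TestAuthenticateSample:
    def test_allowed_genotypes_consistent_with_duroc_caveat(self, standard):
        res = authenticate_sample(
            Genotype(MC1R, "E+", "e"), Genotype(NR6A1, "T", "T"), standard
        )
        assert res["verdict"] == "consistent"
        assert "Duroc" in res["caveat"]

    def test_ep_allele_inconsistent(self, standard):
        res = authenticate_sample(
            Genotype(MC1R, "EP", "e"), Genotype(NR6A1, "T", "T"), standard
        )
        assert res["verdict"] == "inconsistent"

    def test_c_carrier_inconsistent(self, standard):
        res = authenticate_sample(
            Genotype(MC1R, "e", "e"), Genotype(NR6A1, "T", "C"), standard
        )
        assert res["verdict"] == "inconsistent"

    def test_missing_genotype_indeterminate(self, standard):
        res = authenticate_sample(None, Genotype(NR6A1, "T", "T"), standard)
        assert res["verdict"] == "indeterminate"
        assert res["missing"] == ["MC1R"]


# expected published-parity rows: breed -> (delta_combined, ER_MC1R, ER_NR6A1,
# ERc); the Duroc per-allele delta is ambiguous at the third decimal and its
# ER is checked instead.
EXPECTED_ROWS = {
    "Apulo Calabrese": (0.925, 0.075, 0.856, 0.064),
    "Casertana": (0.857, 0.143, 0.938, 0.134),
    "Cinta Senese": (0.955, 0.045, 1.000, 0.045),
    "Nero Siciliano": (0.875, 0.125, 0.718, 0.090),
    "Sarda": (0.638, 0.362, 0.991, 0.359),
    "Wild Boar": (0.053, 0.240, 0.018, 0.004),
    "Italian Large White": (1.000, 0.000, 1.000, 0.000),
    "Italian Landrace": (1.000, 0.000, 1.000, 0.000),
    "Italian Duroc": (None, 0.809, 1.000, 0.809),
    "Pietrain": (1.000, 0.000, 1.000, 0.000),
    "Belgian Landrace": (1.000, 0.000, 1.000, 0.000),
    "Hampshire": (1.000, 0.000, 1.000, 0.000),
}


class TestSummaryTable:
    def test_published_parity_regenerates_all_rows(self, table2_panel):
        rows = {r.breed: r for r in
                build_summary_table(table2_panel, rounding="published_parity")}
        assert set(rows) == set(EXPECTED_ROWS)
        for breed, (d_comb, er_m, er_n, erc) in EXPECTED_ROWS.items():
            got = rows[breed].rounded()
            if d_comb is not None:
                assert got["delta_MC1R_combined"] == pytest.approx(d_comb), breed
            assert got["ER_MC1R"] == pytest.approx(er_m), breed
            assert got["ER_NR6A1"] == pytest.approx(er_n), breed
            assert got["ERc"] == pytest.approx(erc), breed

    def test_mode_auto_selection(self, table2_panel):
        rows = {r.breed: r for r in
                build_summary_table(table2_panel, rounding="published_parity")}
        assert rows["Wild Boar"].mode == "per_allele_average"
        assert rows["Italian Duroc"].mode == "per_allele_average"
        assert rows["Apulo Calabrese"].mode == "combined"

    def test_wild_boar_both_modes_reported(self, table2_panel):
        row = {r.breed: r for r in
               build_summary_table(table2_panel, rounding="published_parity")
               }["Wild Boar"]
        rounded = row.rounded()
        assert rounded["ERc"] == 0.004  # per-allele-average mode (selected)
        assert rounded["ERc_combined"] == 0.017

    def test_pmr_reported_only_with_genotype_data(self, table2_panel, standard):
        gtables = {
            "Italian Duroc": GenotypeCountTable.from_genotype_counts(
                "Italian Duroc", {"MC1R": {"e/e": 30}, "NR6A1": {"T/T": 30}}),
        }
        rows = {r.breed: r for r in build_summary_table(
            table2_panel, genotype_tables=gtables, rounding="published_parity")}
        assert rows["Italian Duroc"].pmr_mc1r == 0.0
        assert rows["Italian Duroc"].pmr_nr6a1 == 0.0
        assert rows["Apulo Calabrese"].pmr_mc1r is None  # no genotype data

    def test_unknown_target_rejected(self, table2_panel):
        with pytest.raises(ValidationError):
            build_summary_table(table2_panel, target="Nonexistent")
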