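"""Shared fixtures: printed-table datasets and an independent Fst oracle."""

from __future__ import annotations

import numpy as np
import pytest

from breedauth import (
    GenotypeCountTable,
    apply_herdbook_filter,
    make_fixture,
    mora_romagnola_standard,
)


@pytest.fixture(scope="session")
def table1_sample():
    """The 357-pig Mora Romagnola breeding-nucleus genotype table."""
    return make_fixture("table1_mora")


@pytest.fixture(scope="session")
def table2_panel():
    """The 13-population breed x locus allele-frequency panel."""
    return make_fixture("table2_panel")


@pytest.fixture(scope="session")
def standard():
    return mora_romagnola_standard()


@pytest.fixture(scope="session")
def compliance_report(table1_sample, standard):
    return apply_herdbook_filter(table1_sample, standard)


@pytest.fixture(scope="session")
def retained_counts(compliance_report):
    """Genotype counts of the 342 retained pigs."""
    return compliance_report.retained_sample().genotype_counts()


@pytest.fixture(scope="session")
def duroc_counts():
    """30 Italian Duroc pigs, fixed e/e and T/T."""
    return GenotypeCountTable.from_genotype_counts(
        "Italian Duroc", {"MC1R": {"e/e": 30}, "NR6A1": {"T/T": 30}}
    )


@pytest.fixture(scope="session")
def large_white_counts():
    """49 Italian Large White pigs, fixed EP/EP and T/T."""
    return GenotypeCountTable.from_genotype_counts(
        "Italian Large White", {"MC1R": {"EP/EP": 49}, "NR6A1": {"T/T": 49}}
    )


# ---------------------------------------------------------------------------
# independent Weir–Cockerham oracle (nested-ANOVA formulation)
# ---------------------------------------------------------------------------

def wc_theta_anova(tables, loci=("MC1R", "NR6A1")) -> float:
    """Two-population Weir–Cockerham theta via the nested-ANOVA route.

    Independent of the closed-form implementation under test: for each allele
    it builds the gene-frequency indicator ANOVA (mean squares among
    populations / among individuals / within individuals) and converts mean
    squares to variance components:

        c = MSG, b = (MSI - MSG) / 2, a = (MSP - MSI) / (2 nc)
    """
    total_a = total_abc = 0.0
    for locus in loci:
        n = [t.n_animals(locus) for t in tables]
        if any(v == 0 for v in n):
            continue
        ac = [t.allele_counts(locus) for t in tables]
        alleles = sorted(set(ac[0]) | set(ac[1]))
        if len(alleles) < 2:
            continue
        r = 2
        n_tot = sum(n)
        nbar = n_tot / r
        nc = (n_tot - sum(v * v for v in n) / n_tot) / (r - 1)
        for allele in alleles:
            # per-individual allele dosages (0, 1 or 2 copies)
            ybar_pop = []
            ssg = 0.0  # within individuals
            ssi = 0.0  # among individuals within populations
            for t, ni in zip(tables, n):
                dosages = []
                for gt, cnt in t.counts[locus].items():
                    dose = gt.alleles.count(allele)
                    dosages.extend([dose] * cnt)
                dosages = np.asarray(dosages, float)
                p_i = dosages.sum() / (2 * ni)
                ybar_pop.append(p_i)
                het = np.sum(dosages == 1)
                ssg += het / 2.0
                ssi += 2.0 * np.sum((dosages / 2.0 - p_i) ** 2)
            pbar = sum(ni * p for ni, p in zip(n, ybar_pop)) / n_tot
            ssp = 2.0 * sum(ni * (p - pbar) ** 2 for ni, p in zip(n, ybar_pop))
            msg = ssg / n_tot
            msi = ssi / (n_tot - r)
            msp = ssp / (r - 1)
            c = msg
            b = (msi - msg) / 2.0
            a = (msp - msi) / (2.0 * nc)
            total_a += a
            total_abc += a + b + c
    if total_abc == 0.0:
        raise ZeroDivisionError("no informative locus")
    return total_a / total_abc


def random_count_table(rng, name, loci_alleles, n_animals):
    """Random genotype counts (not necessarily HWE) for property tests."""
    per_locus = {}
    for locus, alleles in loci_alleles.items():
        labels = [
            f"{a}/{b}" for i, a in enumerate(alleles) for b in alleles[i:]
        ]
        weights = rng.dirichlet(np.ones(len(labels)))
        draws = rng.multinomial(n_animals, weights)
        per_locus[locus] = {
            label: int(k) for label, k in zip(labels, draws) if k
        }
    return GenotypeCountTable.from_genotype_counts(name, per_locus)
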