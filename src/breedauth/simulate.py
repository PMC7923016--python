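"""Synthetic multi-breed genotype data and the printed-panel fixtures.

Two roles:

* :func:`simulate_population` draws diploid genotype samples under
  Hardy–Weinberg proportions from specified allele frequencies (two
  independent allele draws per animal and locus), plus categorical phenotype
  fields with class-specific non-standard rates, so every pipeline stage is
  testable without external data.
* :func:`make_fixture` rebuilds the study's printed datasets: the 357-pig
  Mora Romagnola breeding-nucleus genotype table, the 13-population
  breed x locus allele-frequency panel, and the 74-pig 2010–2014 Mora
  Romagnola allele counts.

Fixture assumptions
-------------------
The genotype table prints marginal counts per locus, not joint genotypes.
The reconstruction makes one documented assumption: the two NR6A1 C-carrier
sows are ``e/e`` at MC1R — this (and only this) reproduces the recomputed
retained-sample frequencies 0.192/0.809.  The single red-coated sow carries
``e/e`` and ``T/T`` and is flagged with the red phenotype; all other adults
carry the standard phenotype.  The one boar among the MC1R-excluded animals
is given the ``ED2/e`` genotype.

Default phenotype rates for simulated young pigs (red coat 8.9 %,
non-standard ears 11 %, absent dorsal mane 9 %) follow the rates observed in
the 2017–2019 phenotyping campaign; adults are simulated as standard.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, NamedTuple

import numpy as np

from .model import (
    AlleleFrequencyTable,
    AnimalRecord,
    DEFAULT_LOCI,
    Genotype,
    Locus,
    MC1R,
    NR6A1,
    PhenotypeRecord,
    PopulationSample,
    ValidationError,
)

__all__ = [
    "PhenotypeRates",
    "BreedSpec",
    "SimulationSpec",
    "simulate_population",
    "make_fixture",
    "FIXTURE_NAMES",
    "TABLE_MC1R_COUNTS",
    "TABLE_NR6A1_COUNTS",
    "FREQUENCY_PANEL",
]


@dataclass(frozen=True)
class PhenotypeRates:
    """Per-class probabilities of the non-standard phenotype states."""

    red_coat: float = 0.0
    nonstandard_ears: float = 0.0
    absent_linea_sparta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("red_coat", "nonstandard_ears", "absent_linea_sparta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} rate {v} outside [0,1]")


#: rates observed in the young-pig phenotyping campaign
YOUNG_RATES = PhenotypeRates(red_coat=0.089, nonstandard_ears=0.11,
                             absent_linea_sparta=0.09)


@dataclass(frozen=True)
class BreedSpec:
    name: str
    n_animals: int
    frequencies: Mapping[str, Mapping[str, float]]  # locus -> allele -> freq

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        for locus, freqs in self.frequencies.items():
            total = float(sum(freqs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"{self.name}/{locus}: frequencies sum to {total}, not 1"
                )
            if any(f < 0 for f in freqs.values()):
                raise ValidationError(f"{self.name}/{locus}: negative frequency")


@dataclass(frozen=True)
class SimulationSpec:
    """Breed specifications plus phenotype rates and a mandatory seed."""

    breeds: tuple[BreedSpec, ...]
    seed: int
    phenotype_rates: Mapping[str, PhenotypeRates] = field(
        default_factory=lambda: {"young": YOUNG_RATES}
    )
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"boar": 0.15, "sow": 0.55, "young": 0.30}
    )
    loci: tuple[Locus, ...] = DEFAULT_LOCI

    def breed(self, name: str) -> BreedSpec:
        for spec in self.breeds:
            if spec.name == name:
                return spec
        raise ValidationError(f"breed {name!r} not in simulation spec")


def simulate_population(spec: SimulationSpec, breed: str) -> PopulationSample:
    """Draw one HWE population sample; deterministic given ``spec.seed``.

    Each animal's two alleles per locus are independent draws from the
    breed's frequency vector.  Sex classes are assigned by the configured
    fractions; phenotype states are drawn per class (classes without
    configured rates get the standard phenotype).
    """
    breed_spec = spec.breed(breed)
    # stable per-breed stream: crc32 is deterministic across processes
    rng = np.random.default_rng((spec.seed, zlib.crc32(breed.encode())))
    n = breed_spec.n_animals
    locus_map = {locus.name: locus for locus in spec.loci}

    classes = sorted(spec.class_fractions)
    probs = np.array([spec.class_fractions[c] for c in classes], float)
    probs = probs / probs.sum()
    sex_classes = rng.choice(classes, size=n, p=probs)

    allele_draws: dict[str, np.ndarray] = {}
    for locus_name, freqs in breed_spec.frequencies.items():
        alleles = list(freqs)
        p = np.array([freqs[a] for a in alleles], float)
        idx = rng.choice(len(alleles), size=(n, 2), p=p / p.sum())
        allele_draws[locus_name] = np.array(alleles, dtype=object)[idx]

    records: list[AnimalRecord] = []
    for i in range(n):
        genotypes = {
            locus_name: Genotype(locus_map[locus_name], draws[i, 0], draws[i, 1])
            for locus_name, draws in allele_draws.items()
        }
        cls = str(sex_classes[i])
        rates = spec.phenotype_rates.get(cls, PhenotypeRates())
        phenotype = PhenotypeRecord(
            coat_colour="red" if rng.random() < rates.red_coat else "black_and_tan",
            ears=(
                str(rng.choice(["half_hanging", "raised"]))
                if rng.random() < rates.nonstandard_ears
                else "bent_forward_parallel"
            ),
            linea_sparta=(
                "absent" if rng.random() < rates.absent_linea_sparta else "present"
            ),
        )
        records.append(
            AnimalRecord(
                animal_id=f"{breed}-{i + 1:04d}",
                breed=breed,
                sex_class=cls,
                genotypes=genotypes,
                phenotype=phenotype,
            )
        )
    return PopulationSample(name=breed, records=records, loci=spec.loci)


# ---------------------------------------------------------------------------
# printed-table fixtures
# ---------------------------------------------------------------------------

#: MC1R genotype counts in the 357 genotyped breeding pigs
TABLE_MC1R_COUNTS: dict[str, int] = {
    "e/e": 225,
    "E+/e": 109,
    "E+/E+": 11,
    "E+/ED2": 5,
    "ED2/e": 5,
    "E+/ED1": 1,
    "ED1/ED2": 1,
}

#: NR6A1 genotype counts in the same 357 pigs
TABLE_NR6A1_COUNTS: dict[str, int] = {"T/T": 355, "T/C": 1, "C/C": 1}

#: breed x locus allele-frequency panel (13 populations, 3-decimal printed
#: values; Mora Romagnola row recomputed on the 342 retained pigs)
FREQUENCY_PANEL: dict[str, tuple[int, dict[str, dict[str, float]]]] = {
    "Mora Romagnola": (342, {
        "MC1R": {"E+": 0.192, "e": 0.809, "ED1": 0.0, "ED2": 0.0, "EP": 0.0},
        "NR6A1": {"T": 1.0, "C": 0.0},
    }),
    "Apulo Calabrese": (101, {
        "MC1R": {"E+": 0.040, "e": 0.035, "ED1": 0.0, "ED2": 0.856, "EP": 0.069},
        "NR6A1": {"T": 0.856, "C": 0.144},
    }),
    "Casertana": (161, {
        "MC1R": {"E+": 0.124, "e": 0.019, "ED1": 0.0, "ED2": 0.767, "EP": 0.090},
        "NR6A1": {"T": 0.938, "C": 0.062},
    }),
    "Cinta Senese": (122, {
        "MC1R": {"E+": 0.004, "e": 0.041, "ED1": 0.004, "ED2": 0.820, "EP": 0.131},
        "NR6A1": {"T": 1.0, "C": 0.0},
    }),
    "Nero Siciliano": (108, {
        "MC1R": {"E+": 0.120, "e": 0.005, "ED1": 0.056, "ED2": 0.630, "EP": 0.190},
        "NR6A1": {"T": 0.718, "C": 0.282},
    }),
    "Sarda": (58, {
        "MC1R": {"E+": 0.302, "e": 0.060, "ED1": 0.060, "ED2": 0.578, "EP": 0.0},
        "NR6A1": {"T": 0.991, "C": 0.009},
    }),
    "Wild Boar": (113, {
        "MC1R": {"E+": 0.925, "e": 0.022, "ED1": 0.0, "ED2": 0.004, "EP": 0.049},
        "NR6A1": {"T": 0.018, "C": 0.982},
    }),
    "Italian Large White": (49, {
        "MC1R": {"E+": 0.0, "e": 0.0, "ED1": 0.0, "ED2": 0.0, "EP": 1.0},
        "NR6A1": {"T": 1.0, "C": 0.0},
    }),
    "Italian Landrace": (44, {
        "MC1R": {"E+": 0.0, "e": 0.0, "ED1": 0.0, "ED2": 0.0, "EP": 1.0},
        "NR6A1": {"T": 1.0, "C": 0.0},
    }),
    "Italian Duroc": (30, {
        "MC1R": {"E+": 0.0, "e": 1.0, "ED1": 0.0, "ED2": 0.0, "EP": 0.0},
        "NR6A1": {"T": 1.0, "C": 0.0},
    }),
    "Pietrain": (26, {
        "MC1R": {"E+": 0.0, "e": 0.0, "ED1": 0.0, "ED2": 0.0, "EP": 1.0},
        "NR6A1": {"T": 1.0, "C": 0.0},
    }),
    "Belgian Landrace": (31, {
        "MC1R": {"E+": 0.0, "e": 0.0, "ED1": 0.0, "ED2": 0.0, "EP": 1.0},
        "NR6A1": {"T": 1.0, "C": 0.0},
    }),
    "Hampshire": (18, {
        "MC1R": {"E+": 0.0, "e": 0.0, "ED1": 0.0, "ED2": 1.0, "EP": 0.0},
        "NR6A1": {"T": 1.0, "C": 0.0},
    }),
}


class AlleleCountFixture(NamedTuple):
    """Allele counts for a population known only at the allele level."""

    name: str
    n_animals: int
    counts: dict[str, dict[str, int]]  # locus -> allele -> count

    def frequencies(self) -> dict[str, dict[str, Fraction]]:
        return {
            locus: {a: Fraction(c, 2 * self.n_animals) for a, c in per.items()}
            for locus, per in self.counts.items()
        }


FIXTURE_NAMES = ("table1_mora", "table2_panel", "mora_2010_2014")


def _build_table1_sample() -> PopulationSample:
    """357 breeding pigs with the printed marginal genotype counts.

    110 boars and 247 sows; the ED2/e boar, the two C-carrier sows (assumed
    e/e at MC1R) and the red-coated sow are placed explicitly.
    """
    standard_pheno = PhenotypeRecord(
        coat_colour="black_and_tan", ears="bent_forward_parallel",
        linea_sparta="present",
    )
    red_pheno = PhenotypeRecord(
        coat_colour="red", ears="bent_forward_parallel", linea_sparta="present"
    )
    records: list[AnimalRecord] = []
    counter = [0]

    def add(mc1r_label: str, nr6a1_label: str, sex_class: str,
            phenotype: PhenotypeRecord = standard_pheno) -> None:
        counter[0] += 1
        records.append(
            AnimalRecord(
                animal_id=f"MR{counter[0]:04d}",
                breed="Mora Romagnola",
                sex_class=sex_class,
                genotypes={
                    "MC1R": Genotype.from_string(MC1R, mc1r_label),
                    "NR6A1": Genotype.from_string(NR6A1, nr6a1_label),
                },
                phenotype=phenotype,
            )
        )

    # special animals first
    add("e/e", "T/C", "sow")           # C-carrier sow (assumed e/e at MC1R)
    add("e/e", "C/C", "sow")           # C-carrier sow (assumed e/e at MC1R)
    add("e/e", "T/T", "sow", red_pheno)  # the red-coated sow
    add("ED2/e", "T/T", "boar")        # the one boar with a non-specific allele
    remaining = {
        "e/e": 225 - 3,
        "E+/e": 109,
        "E+/E+": 11,
        "E+/ED2": 5,
        "ED2/e": 5 - 1,
        "E+/ED1": 1,
        "ED1/ED2": 1,
    }
    n_boars_left = 110 - 1
    for label, count in remaining.items():
        for _ in range(count):
            if n_boars_left > 0 and label in ("e/e", "E+/e", "E+/E+"):
                sex = "boar"
                n_boars_left -= 1
            else:
                sex = "sow"
            add(label, "T/T", sex)
    sample = PopulationSample(name="Mora Romagnola", records=records,
                              loci=(MC1R, NR6A1))
    assert len(sample) == 357
    return sample


def make_fixture(name: str):
    """Return a printed-data fixture.

    * ``"table1_mora"`` — :class:`PopulationSample` of the 357 genotyped
      breeding pigs;
    * ``"table2_panel"`` — :class:`AlleleFrequencyTable` of the 13-population
      panel (printed 3-decimal values);
    * ``"mora_2010_2014"`` — :class:`AlleleCountFixture` with the earlier
      sample's allele counts (74 pigs: 26 E+ / 122 e at MC1R, all T at
      NR6A1).
    """
    if name == "table1_mora":
        return _build_table1_sample()
    if name == "table2_panel":
        entries = {
            breed: {
                locus: (dict(freqs), n)
                for locus, freqs in per_locus.items()
            }
            for breed, (n, per_locus) in FREQUENCY_PANEL.items()
        }
        return AlleleFrequencyTable(entries=entries)
    if name == "mora_2010_2014":
        return AlleleCountFixture(
            name="Mora Romagnola (2010-2014)",
            n_animals=74,
            counts={"MC1R": {"E+": 26, "e": 122}, "NR6A1": {"T": 148}},
        )
    raise ValidationError(f"unknown fixture {name!r} (known: {FIXTURE_NAMES})")
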