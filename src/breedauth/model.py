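"""Domain types for two-marker breed genotyping data.

The package works with diploid genotype records at a small number of
candidate-gene loci (by default the pig coat-colour locus *MC1R* / Extension
and the vertebral-number gene *NR6A1*).  Frequencies derived from counts are
kept as exact rationals (:class:`fractions.Fraction`) so that per-locus allele
frequencies always sum to one; only externally read tables carry float
rounding error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional

__all__ = [
    "BreedAuthError",
    "FormatError",
    "ValidationError",
    "AmbiguousCallError",
    "InconsistentPatternError",
    "UnsupportedFormatError",
    "Locus",
    "Genotype",
    "PhenotypeRecord",
    "AnimalRecord",
    "PopulationSample",
    "GenotypeCountTable",
    "AlleleFrequencyTable",
    "MC1R",
    "NR6A1",
    "DEFAULT_LOCI",
    "MISSING_TOKENS",
    "COAT_COLOURS",
    "EAR_POSITIONS",
    "LINEA_SPARTA",
    "SEX_CLASSES",
]


class BreedAuthError(Exception):
    """Base class for all package errors."""


class FormatError(BreedAuthError):
    """A file does not conform to the expected layout."""


class ValidationError(BreedAuthError):
    """Input data violates a domain invariant."""


class AmbiguousCallError(BreedAuthError):
    """An allele call cannot be made because a required assay result is unknown."""


class InconsistentPatternError(BreedAuthError):
    """A restriction-assay pattern contradicts the published allele truth table."""


class UnsupportedFormatError(BreedAuthError):
    """The data cannot be represented in the requested output format."""


# Controlled vocabularies for phenotype and class fields.
COAT_COLOURS = ("black_and_tan", "red", "other")
EAR_POSITIONS = ("bent_forward_parallel", "half_hanging", "raised", "other")
LINEA_SPARTA = ("present", "absent")
SEX_CLASSES = ("boar", "sow", "young")

#: tokens interpreted as "missing" when reading delimited genotype tables
MISSING_TOKENS = frozenset({"", "NA", "na", ".", "-", "0"})


@dataclass(frozen=True)
class Locus:
    """A polymorphic marker with a fixed, ordered allele vocabulary.

    Parameters
    ----------
    name:
        Short locus symbol (``"MC1R"``).
    alleles:
        Ordered tuple of allowed allele symbols.
    metadata:
        Free-text variant descriptor (e.g. ``"g.299084751C>T (p.P192L)"``).
    """

    name: str
    alleles: tuple[str, ...]
    metadata: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("locus name must be non-empty")
        if len(self.alleles) < 2:
            raise ValidationError(f"locus {self.name}: need >=2 alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValidationError(f"locus {self.name}: duplicate allele codes")
        if any(not a for a in self.alleles):
            raise ValidationError(f"locus {self.name}: empty allele symbol")

    def validate_allele(self, symbol: str) -> str:
        if symbol not in self.alleles:
            raise ValidationError(
                f"allele {symbol!r} is not defined for locus {self.name} "
                f"(known: {', '.join(self.alleles)})"
            )
        return symbol


#: Extension locus: five classical coat-colour alleles.
MC1R = Locus(
    "MC1R",
    ("E+", "ED1", "ED2", "EP", "e"),
    metadata="Extension locus; E+ wild type, ED1/ED2 dominant black, "
    "EP spotted/white, e recessive red",
)

#: vertebral-number gene; T is the domestic allele, C the wild-boar allele.
NR6A1 = Locus("NR6A1", ("C", "T"), metadata="g.299084751C>T (p.P192L)")

DEFAULT_LOCI: tuple[Locus, ...] = (MC1R, NR6A1)


@dataclass(frozen=True)
class Genotype:
    """An unordered diploid allele pair at one locus.

    ``Genotype("MC1R", "e", "E+") == Genotype("MC1R", "E+", "e")`` — the pair
    is canonicalised (sorted) on construction so equality, hashing and
    counting ignore allele order.
    """

    locus: str
    alleles: tuple[str, str]

    def __init__(self, locus, allele_a: str, allele_b: str):
        locus_name = locus.name if isinstance(locus, Locus) else str(locus)
        if isinstance(locus, Locus):
            locus.validate_allele(allele_a)
            locus.validate_allele(allele_b)
        pair = tuple(sorted((allele_a, allele_b)))
        object.__setattr__(self, "locus", locus_name)
        object.__setattr__(self, "alleles", pair)

    @property
    def allele_a(self) -> str:
        return self.alleles[0]

    @property
    def allele_b(self) -> str:
        return self.alleles[1]

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    @classmethod
    def from_string(cls, locus, text: str) -> "Genotype":
        """Parse ``"E+/e"`` style genotype labels."""
        parts = text.split("/")
        if len(parts) != 2:
            raise FormatError(f"cannot parse genotype {text!r} (expected 'a/b')")
        return cls(locus, parts[0].strip(), parts[1].strip())

    def __str__(self) -> str:
        return f"{self.alleles[0]}/{self.alleles[1]}"


@dataclass(frozen=True)
class PhenotypeRecord:
    """The three Herd-Book morphological descriptors.

    Any field may be ``None`` meaning "not recorded"; known values must come
    from the controlled vocabularies above.
    """

    coat_colour: Optional[str] = None
    ears: Optional[str] = None
    linea_sparta: Optional[str] = None

    def __post_init__(self) -> None:
        for value, vocab, label in (
            (self.coat_colour, COAT_COLOURS, "coat_colour"),
            (self.ears, EAR_POSITIONS, "ears"),
            (self.linea_sparta, LINEA_SPARTA, "linea_sparta"),
        ):
            if value is not None and value not in vocab:
                raise ValidationError(f"unknown {label} value {value!r}")


@dataclass
class AnimalRecord:
    """One genotyped (and optionally phenotyped) animal.

    Missing genotypes are explicit: a locus absent from ``genotypes`` means
    "not typed" and excludes the animal from that locus's statistics only.
    """

    animal_id: str
    breed: str
    sex_class: str
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    phenotype: Optional[PhenotypeRecord] = None

    def __post_init__(self) -> None:
        if not self.animal_id:
            raise ValidationError("animal_id must be non-empty")
        if self.sex_class not in SEX_CLASSES:
            raise ValidationError(
                f"animal {self.animal_id}: unknown class {self.sex_class!r}"
            )

    @property
    def is_adult(self) -> bool:
        return self.sex_class in ("boar", "sow")


@dataclass
class PopulationSample:
    """A named collection of animal records for one breed/population."""

    name: str
    records: list[AnimalRecord]
    loci: tuple[Locus, ...] = DEFAULT_LOCI

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        known = {locus.name for locus in self.loci}
        seen: set[str] = set()
        for rec in self.records:
            if rec.animal_id in seen:
                raise ValidationError(f"duplicate animal_id {rec.animal_id!r}")
            seen.add(rec.animal_id)
            for locus_name in rec.genotypes:
                if locus_name not in known:
                    raise ValidationError(
                        f"animal {rec.animal_id}: genotype at undeclared locus "
                        f"{locus_name!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def locus(self, name: str) -> Locus:
        for locus in self.loci:
            if locus.name == name:
                return locus
        raise KeyError(name)

    def subset(self, animal_ids: Iterable[str], name: Optional[str] = None) -> "PopulationSample":
        wanted = set(animal_ids)
        return PopulationSample(
            name=name or self.name,
            records=[r for r in self.records if r.animal_id in wanted],
            loci=self.loci,
        )

    def genotype_counts(self) -> "GenotypeCountTable":
        return GenotypeCountTable.from_sample(self)


@dataclass
class GenotypeCountTable:
    """Per-locus genotype counts for one population.

    ``n_animals[locus]`` counts animals actually typed at that locus, so
    genotype counts sum to ``n_animals`` and allele counts to ``2*n_animals``.
    """

    name: str
    counts: dict[str, Counter]
    loci: tuple[Locus, ...] = DEFAULT_LOCI

    @classmethod
    def from_sample(cls, sample: PopulationSample) -> "GenotypeCountTable":
        counts: dict[str, Counter] = {locus.name: Counter() for locus in sample.loci}
        for rec in sample.records:
            for locus_name, gt in rec.genotypes.items():
                counts[locus_name][gt] += 1
        return cls(name=sample.name, counts=counts, loci=sample.loci)

    @classmethod
    def from_genotype_counts(
        cls,
        name: str,
        per_locus: Mapping[str, Mapping[str, int]],
        loci: tuple[Locus, ...] = DEFAULT_LOCI,
    ) -> "GenotypeCountTable":
        """Build from ``{"MC1R": {"e/e": 225, "E+/e": 109, ...}, ...}``."""
        locus_map = {locus.name: locus for locus in loci}
        counts: dict[str, Counter] = {}
        for locus_name, table in per_locus.items():
            locus = locus_map[locus_name]
            ctr: Counter = Counter()
            for label, n in table.items():
                if n < 0:
                    raise ValidationError(f"negative genotype count for {label}")
                if n:
                    ctr[Genotype.from_string(locus, label)] += n
            counts[locus_name] = ctr
        return cls(name=name, counts=counts, loci=loci)

    def n_animals(self, locus_name: str) -> int:
        return sum(self.counts.get(locus_name, Counter()).values())

    def allele_counts(self, locus_name: str) -> Counter:
        out: Counter = Counter()
        for gt, n in self.counts.get(locus_name, Counter()).items():
            out[gt.alleles[0]] += n
            out[gt.alleles[1]] += n
        return out

    def observed_alleles(self, locus_name: str) -> tuple[str, ...]:
        locus = next(l for l in self.loci if l.name == locus_name)
        present = self.allele_counts(locus_name)
        return tuple(a for a in locus.alleles if present.get(a, 0) > 0)

    def heterozygote_count(self, locus_name: str, allele: str) -> int:
        """Number of animals heterozygous *and* carrying ``allele``."""
        return sum(
            n
            for gt, n in self.counts.get(locus_name, Counter()).items()
            if not gt.is_homozygous and allele in gt.alleles
        )


@dataclass
class AlleleFrequencyTable:
    """Breed x locus allele-frequency panel with sample sizes.

    ``entries[breed][locus] = (freqs, n_animals)`` where ``freqs`` maps allele
    symbol to frequency (Fraction when derived from counts, float when read
    from a file).
    """

    entries: dict[str, dict[str, tuple[dict[str, Fraction | float], int]]]

    #: sum-to-one tolerance for externally read tables; printed tables drift
    #: by rounding (e.g. 0.192 + 0.809 = 1.001).
    READ_TOLERANCE = 0.015

    def breeds(self) -> list[str]:
        return list(self.entries)

    def loci(self) -> list[str]:
        seen: list[str] = []
        for per_breed in self.entries.values():
            for locus in per_breed:
                if locus not in seen:
                    seen.append(locus)
        return seen

    def frequencies(self, breed: str, locus: str) -> dict[str, Fraction | float]:
        return self.entries[breed][locus][0]

    def n_animals(self, breed: str, locus: str) -> int:
        return self.entries[breed][locus][1]

    def validate(self, tolerance: float = READ_TOLERANCE, strict: bool = True) -> list[str]:
        """Check [0,1] range and per-breed-locus sum-to-one.

        Returns warning strings for sum deviations; raises ValidationError for
        out-of-range values (always) and sum violations when ``strict``.
        """
        warnings: list[str] = []
        for breed, per_breed in self.entries.items():
            for locus, (freqs, n) in per_breed.items():
                if n < 1:
                    raise ValidationError(f"{breed}/{locus}: n_animals must be >= 1")
                for allele, f in freqs.items():
                    if not (0 <= float(f) <= 1):
                        raise ValidationError(
                            f"{breed}/{locus}: frequency of {allele} out of [0,1]"
                        )
                dev = abs(float(sum(freqs.values())) - 1.0)
                if dev > tolerance:
                    msg = (
                        f"{breed}/{locus}: frequencies sum to "
                        f"{float(sum(freqs.values())):.4f} (deviation {dev:.4f} "
                        f"> tolerance {tolerance})"
                    )
                    if strict:
                        raise ValidationError(msg)
                    warnings.append(msg)
        return warnings

    @classmethod
    def from_count_tables(cls, tables: Iterable[GenotypeCountTable]) -> "AlleleFrequencyTable":
        """Exact (rational) frequencies derived from genotype counts."""
        entries: dict[str, dict[str, tuple[dict[str, Fraction | float], int]]] = {}
        for table in tables:
            per_breed: dict[str, tuple[dict[str, Fraction | float], int]] = {}
            for locus in table.loci:
                n = table.n_animals(locus.name)
                if n == 0:
                    continue
                allele_counts = table.allele_counts(locus.name)
                freqs = {
                    allele: Fraction(allele_counts.get(allele, 0), 2 * n)
                    for allele in locus.alleles
                }
                per_breed[locus.name] = (freqs, n)
            entries[table.name] = per_breed
        return cls(entries=entries)

    def frequency_vector(
        self, breed: str, loci: Iterable[str], allele_order: Mapping[str, tuple[str, ...]]
    ) -> list[float]:
        """Concatenated per-locus frequency vector (absent allele -> 0.0)."""
        vec: list[float] = []
        for locus in loci:
            freqs = self.entries[breed].get(locus, ({}, 0))[0]
            for allele in allele_order[locus]:
                vec.append(float(freqs.get(allele, 0.0)))
        return vec
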