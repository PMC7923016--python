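"""Breed-standard encoding: PCR-RFLP allele calling and Herd-Book compliance.

Allele calling
--------------
The five Extension-locus (*MC1R*) alleles are resolved by three restriction
assays plus a 2-bp indel sized on a capillary sequencer:

* *Hha*I cuts every allele except ``e`` — an uncut pattern calls ``e``;
* *Bst*UI cuts every allele except ``e`` and ``ED1`` — with *Hha*I cut, an
  uncut *Bst*UI pattern calls ``ED1``;
* *Bsp*HI cuts ``ED2`` and ``EP`` but not ``E+`` — an uncut pattern calls
  ``E+``;
* the indel fragment distinguishes ``ED2`` (168 bp) from ``EP`` (170 bp).

The decision tree is consulted in that order, so the branches whose enzyme
behaviour is unpublished (e.g. *Bsp*HI on ``e``) are never reached for those
alleles; a pattern that contradicts the published truth table raises
:class:`InconsistentPatternError` instead of guessing.

The *NR6A1* assay is a single *Msp*I digestion that cuts when the wild-type
(C) allele is present.

Compliance
----------
The redefined Herd-Book standard admits *MC1R* genotypes ``e/e``, ``E+/e``,
``E+/E+`` and *NR6A1* ``T/T``, plus the three morphological descriptors
(black-and-tan coat, ears bent forward and parallel, dorsal bristle mane
present).  Red coat, non-standard ears and an absent mane are tolerated in
young animals.  Exclusion reasons are evaluated in fixed precedence —
phenotype, then MC1R, then NR6A1 — and each excluded animal is counted once
under the first failing rule (all failing rules are still recorded).
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .model import (
    AmbiguousCallError,
    AnimalRecord,
    Genotype,
    InconsistentPatternError,
    Locus,
    MC1R,
    NR6A1,
    PopulationSample,
    ValidationError,
)

__all__ = [
    "MC1RAssayPattern",
    "call_mc1r_allele",
    "call_nr6a1_allele",
    "BreedStandard",
    "mora_romagnola_standard",
    "ComplianceDecision",
    "ComplianceReport",
    "check_record",
    "apply_herdbook_filter",
    "REASON_PHENOTYPE",
    "REASON_MC1R",
    "REASON_NR6A1",
]

CUT = "cut"
UNCUT = "uncut"
UNKNOWN = "unknown"

REASON_PHENOTYPE = "phenotype_coat"
REASON_MC1R = "genotype_MC1R"
REASON_NR6A1 = "genotype_NR6A1"
_REASON_ORDER = (REASON_PHENOTYPE, REASON_MC1R, REASON_NR6A1)

# Published digestion truth table per allele; None = behaviour unpublished.
_MC1R_TRUTH: dict[str, dict[str, object]] = {
    "e": {"hhai": UNCUT, "bstui": UNCUT, "bsphi": None, "indel": None},
    "ED1": {"hhai": CUT, "bstui": UNCUT, "bsphi": None, "indel": None},
    "E+": {"hhai": CUT, "bstui": CUT, "bsphi": UNCUT, "indel": None},
    "ED2": {"hhai": CUT, "bstui": CUT, "bsphi": CUT, "indel": 168},
    "EP": {"hhai": CUT, "bstui": CUT, "bsphi": CUT, "indel": 170},
}


@dataclass(frozen=True)
class MC1RAssayPattern:
    """Scored single-allele restriction pattern for the MC1R assays."""

    bsphi_cut: str = UNKNOWN
    hhai_cut: str = UNKNOWN
    bstui_cut: str = UNKNOWN
    indel_fragment_bp: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("bsphi_cut", "hhai_cut", "bstui_cut"):
            value = getattr(self, name)
            if value not in (CUT, UNCUT, UNKNOWN):
                raise ValidationError(f"{name} must be cut/uncut/unknown, got {value!r}")
        if self.indel_fragment_bp not in (None, 168, 170):
            raise ValidationError("indel fragment must be 168 or 170 bp (or unknown)")
        if (
            self.bsphi_cut == UNKNOWN
            and self.hhai_cut == UNKNOWN
            and self.bstui_cut == UNKNOWN
            and self.indel_fragment_bp is None
        ):
            raise ValidationError("at least one assay result must be known")


def _check_consistency(pattern: MC1RAssayPattern, allele: str) -> None:
    truth = _MC1R_TRUTH[allele]
    observed = {
        "hhai": None if pattern.hhai_cut == UNKNOWN else pattern.hhai_cut,
        "bstui": None if pattern.bstui_cut == UNKNOWN else pattern.bstui_cut,
        "bsphi": None if pattern.bsphi_cut == UNKNOWN else pattern.bsphi_cut,
        "indel": pattern.indel_fragment_bp,
    }
    for assay, expected in truth.items():
        seen = observed[assay]
        if expected is not None and seen is not None and seen != expected:
            raise InconsistentPatternError(
                f"pattern inconsistent with allele {allele}: {assay} observed "
                f"{seen!r}, published behaviour {expected!r}"
            )


def call_mc1r_allele(pattern: MC1RAssayPattern) -> str:
    """Resolve a single-allele MC1R restriction pattern to an allele symbol."""
    if pattern.hhai_cut == UNKNOWN:
        raise AmbiguousCallError("HhaI result required but unknown")
    if pattern.hhai_cut == UNCUT:
        allele = "e"
    else:
        if pattern.bstui_cut == UNKNOWN:
            raise AmbiguousCallError("BstUI result required but unknown")
        if pattern.bstui_cut == UNCUT:
            allele = "ED1"
        else:
            if pattern.bsphi_cut == UNKNOWN:
                raise AmbiguousCallError("BspHI result required but unknown")
            if pattern.bsphi_cut == UNCUT:
                allele = "E+"
            else:
                if pattern.indel_fragment_bp is None:
                    raise AmbiguousCallError(
                        "indel fragment size required but unknown"
                    )
                allele = "ED2" if pattern.indel_fragment_bp == 168 else "EP"
    _check_consistency(pattern, allele)
    return MC1R.validate_allele(allele)


def call_nr6a1_allele(mspi_cut: str) -> str:
    """MspI cuts when the wild-type allele is present: cut -> C, uncut -> T."""
    if mspi_cut == CUT:
        return "C"
    if mspi_cut == UNCUT:
        return "T"
    raise AmbiguousCallError("MspI result required but unknown")


@dataclass
class BreedStandard:
    """Allowed genotypes per locus plus phenotype rules per age class."""

    name: str
    allowed_genotypes: dict[str, frozenset]
    #: per age class, per trait, the set of acceptable values (a trait absent
    #: from the mapping is unconstrained for that class)
    phenotype_rules: dict[str, dict[str, frozenset]]

    def __post_init__(self) -> None:
        for locus, allowed in self.allowed_genotypes.items():
            if not allowed:
                raise ValidationError(f"standard {self.name}: empty allowed set for {locus}")

    def genotype_allowed(self, gt: Genotype) -> bool:
        allowed = self.allowed_genotypes.get(gt.locus)
        return allowed is None or gt in allowed

    def phenotype_violations(self, record: AnimalRecord) -> list[str]:
        rules = self.phenotype_rules.get(
            "adult" if record.is_adult else record.sex_class, {}
        )
        if record.phenotype is None:
            return []
        violations = []
        for trait, allowed in rules.items():
            value = getattr(record.phenotype, trait)
            if value is not None and value not in allowed:
                violations.append(trait)
        return violations

    def to_yaml(self, path) -> None:
        data = {
            "name": self.name,
            "allowed_genotypes": {
                locus: sorted(str(gt) for gt in allowed)
                for locus, allowed in self.allowed_genotypes.items()
            },
            "phenotype_rules": {
                cls: {trait: sorted(vals) for trait, vals in rules.items()}
                for cls, rules in self.phenotype_rules.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path, loci: tuple[Locus, ...] = (MC1R, NR6A1)) -> "BreedStandard":
        data = yaml.safe_load(Path(path).read_text())
        locus_map = {locus.name: locus for locus in loci}
        allowed = {
            locus: frozenset(
                Genotype.from_string(locus_map[locus], label) for label in labels
            )
            for locus, labels in data["allowed_genotypes"].items()
        }
        rules = {
            cls: {trait: frozenset(vals) for trait, vals in traits.items()}
            for cls, traits in data.get("phenotype_rules", {}).items()
        }
        return cls(name=data.get("name", "standard"), allowed_genotypes=allowed,
                   phenotype_rules=rules)


def mora_romagnola_standard() -> BreedStandard:
    """The redefined Mora Romagnola Herd-Book standard.

    Adults must be black and tan with ears bent forward and parallel and the
    dorsal mane present; young animals are unconstrained (red coat,
    non-standard ears and absent mane are tolerated until adulthood).
    """
    return BreedStandard(
        name="Mora Romagnola",
        allowed_genotypes={
            "MC1R": frozenset(
                Genotype(MC1R, *pair) for pair in (("e", "e"), ("E+", "e"), ("E+", "E+"))
            ),
            "NR6A1": frozenset({Genotype(NR6A1, "T", "T")}),
        },
        phenotype_rules={
            "adult": {
                "coat_colour": frozenset({"black_and_tan"}),
                "ears": frozenset({"bent_forward_parallel"}),
                "linea_sparta": frozenset({"present"}),
            },
            "young": {},
        },
    )


@dataclass(frozen=True)
class ComplianceDecision:
    """Per-animal verdict: retained / excluded / indeterminate."""

    animal_id: str
    status: str  # retained | excluded | indeterminate
    reasons: tuple[str, ...] = ()  # all failing rules, precedence order
    missing_loci: tuple[str, ...] = ()

    @property
    def primary_reason(self) -> Optional[str]:
        return self.reasons[0] if self.reasons else None


def check_record(record: AnimalRecord, standard: BreedStandard) -> ComplianceDecision:
    """Evaluate one animal against the standard.

    A missing genotype at a standard locus makes the status ``indeterminate``
    (distinct from exclusion).  Reasons accumulate in fixed precedence:
    phenotype, MC1R, NR6A1.
    """
    missing = tuple(
        locus for locus in standard.allowed_genotypes if locus not in record.genotypes
    )
    reasons: list[str] = []
    if standard.phenotype_violations(record):
        reasons.append(REASON_PHENOTYPE)
    for locus, reason in (("MC1R", REASON_MC1R), ("NR6A1", REASON_NR6A1)):
        if locus not in standard.allowed_genotypes:
            continue
        gt = record.genotypes.get(locus)
        if gt is not None and not standard.genotype_allowed(gt):
            reasons.append(reason)
    if missing and not reasons:
        return ComplianceDecision(record.animal_id, "indeterminate",
                                  missing_loci=missing)
    status = "excluded" if reasons else "retained"
    return ComplianceDecision(record.animal_id, status, tuple(reasons), missing)


@dataclass
class ComplianceReport:
    """Partition of a sample into retained / excluded / indeterminate."""

    standard_name: str
    retained: list[str]
    excluded: list[ComplianceDecision]
    indeterminate: list[ComplianceDecision]
    counts_by_reason: Counter = field(default_factory=Counter)
    _retained_sample: Optional[PopulationSample] = None

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def retained_sample(self) -> PopulationSample:
        if self._retained_sample is None:
            raise ValidationError("report was built without the source sample")
        return self._retained_sample

    def to_csv(self, path) -> None:
        with Path(path).open("w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["animal_id", "status", "reasons"])
            for animal_id in self.retained:
                writer.writerow([animal_id, "retained", ""])
            for dec in self.excluded:
                writer.writerow([dec.animal_id, "excluded", ";".join(dec.reasons)])
            for dec in self.indeterminate:
                writer.writerow([dec.animal_id, "indeterminate",
                                 "missing:" + ";".join(dec.missing_loci)])

    def summary(self) -> dict:
        return {
            "standard": self.standard_name,
            "n_retained": len(self.retained),
            "n_excluded": self.n_excluded,
            "n_indeterminate": len(self.indeterminate),
            "counts_by_reason": dict(self.counts_by_reason),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def apply_herdbook_filter(
    sample: PopulationSample, standard: BreedStandard
) -> ComplianceReport:
    """Apply the standard to every record; each exclusion counts once under
    its first failing rule (precedence phenotype -> MC1R -> NR6A1)."""
    if not sample.records:
        raise ValidationError("cannot filter an empty sample")
    retained: list[str] = []
    excluded: list[ComplianceDecision] = []
    indeterminate: list[ComplianceDecision] = []
    counts: Counter = Counter()
    for record in sample.records:
        decision = check_record(record, standard)
        if decision.status == "retained":
            retained.append(record.animal_id)
        elif decision.status == "excluded":
            excluded.append(decision)
            counts[decision.primary_reason] += 1
        else:
            indeterminate.append(decision)
    report = ComplianceReport(
        standard_name=standard.name,
        retained=retained,
        excluded=excluded,
        indeterminate=indeterminate,
        counts_by_reason=counts,
        _retained_sample=sample.subset(retained),
    )
    assert len(report.retained) + len(excluded) + len(indeterminate) == len(sample)
    return report
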