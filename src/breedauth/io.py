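"""Readers and writers for the delimited genotype/frequency formats and GENEPOP.

Formats
-------
Genotype table (CSV, comma default, tab via ``sep="\\t"``)::

    animal_id,breed,class,MC1R_a1,MC1R_a2,NR6A1_a1,NR6A1_a2[,coat_colour,ears,linea_sparta]

Frequency table (long form)::

    breed,n,locus,allele,freq

GENEPOP flat format (4-digit diploid encoding) for interoperability with the
GENEPOP family of programs.  Allele codes are assigned per locus by
lexicographic order of the allele symbols (01, 02, ...); the mapping is
recorded on the title line so runs are reproducible.  Missing genotypes are
encoded ``0000``.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .model import (
    AlleleFrequencyTable,
    AnimalRecord,
    FormatError,
    Genotype,
    Locus,
    MISSING_TOKENS,
    PhenotypeRecord,
    PopulationSample,
    UnsupportedFormatError,
    ValidationError,
    DEFAULT_LOCI,
)

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "write_genepop",
    "read_genepop",
    "read_frequency_table",
    "write_frequency_table",
    "genepop_allele_codes",
]

_PHENO_COLS = ("coat_colour", "ears", "linea_sparta")


def _locus_columns(loci: Sequence[Locus]) -> list[str]:
    cols: list[str] = []
    for locus in loci:
        cols += [f"{locus.name}_a1", f"{locus.name}_a2"]
    return cols


def read_genotype_table(
    path, locus_defs: Sequence[Locus] = DEFAULT_LOCI, sep: str = ","
) -> PopulationSample:
    """Read a delimited genotype table into a :class:`PopulationSample`.

    A missing-value token in either allele column yields a missing genotype at
    that locus; an allele symbol outside the locus definition raises
    :class:`ValidationError` naming the row and locus.
    """
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter=sep)
        header = reader.fieldnames
        if header is None:
            raise FormatError(f"{path}: empty file")
        required = ["animal_id", "breed", "class"] + _locus_columns(locus_defs)
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        has_pheno = all(c in header for c in _PHENO_COLS)

        records: list[AnimalRecord] = []
        breeds: list[str] = []
        for line_no, row in enumerate(reader, start=2):
            genotypes: dict[str, Genotype] = {}
            for locus in locus_defs:
                a1 = (row[f"{locus.name}_a1"] or "").strip()
                a2 = (row[f"{locus.name}_a2"] or "").strip()
                if a1 in MISSING_TOKENS or a2 in MISSING_TOKENS:
                    continue
                try:
                    genotypes[locus.name] = Genotype(locus, a1, a2)
                except ValidationError as exc:
                    raise ValidationError(f"{path}:{line_no} ({locus.name}): {exc}") from exc
            phenotype = None
            if has_pheno:
                values = {c: (row[c] or "").strip() or None for c in _PHENO_COLS}
                if any(values.values()):
                    try:
                        phenotype = PhenotypeRecord(**values)
                    except ValidationError as exc:
                        raise ValidationError(f"{path}:{line_no}: {exc}") from exc
            rec = AnimalRecord(
                animal_id=row["animal_id"].strip(),
                breed=row["breed"].strip(),
                sex_class=row["class"].strip(),
                genotypes=genotypes,
                phenotype=phenotype,
            )
            records.append(rec)
            if rec.breed not in breeds:
                breeds.append(rec.breed)

    name = breeds[0] if len(breeds) == 1 else path.stem
    return PopulationSample(name=name, records=records, loci=tuple(locus_defs))


def write_genotype_table(sample: PopulationSample, path, sep: str = ",") -> None:
    """Inverse of :func:`read_genotype_table` (phenotype columns always written)."""
    path = Path(path)
    cols = ["animal_id", "breed", "class"] + _locus_columns(sample.loci) + list(_PHENO_COLS)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=sep)
        writer.writerow(cols)
        for rec in sample.records:
            row = [rec.animal_id, rec.breed, rec.sex_class]
            for locus in sample.loci:
                gt = rec.genotypes.get(locus.name)
                row += list(gt.alleles) if gt else ["", ""]
            ph = rec.phenotype
            row += [
                (ph.coat_colour if ph else "") or "",
                (ph.ears if ph else "") or "",
                (ph.linea_sparta if ph else "") or "",
            ]
            writer.writerow(row)


def genepop_allele_codes(locus: Locus) -> dict[str, str]:
    """2-digit numeric codes by lexicographic symbol order (deterministic)."""
    if len(locus.alleles) > 99:
        raise UnsupportedFormatError(
            f"locus {locus.name}: {len(locus.alleles)} alleles exceed the "
            "2-digit GENEPOP encoding"
        )
    return {a: f"{i:02d}" for i, a in enumerate(sorted(locus.alleles), start=1)}


def write_genepop(
    samples: Sequence[PopulationSample], path, title: Optional[str] = None
) -> None:
    """Write populations to a GENEPOP flat file (4-digit diploid encoding)."""
    if not samples:
        raise ValidationError("no populations to write")
    loci = samples[0].loci
    for sample in samples[1:]:
        if tuple(l.name for l in sample.loci) != tuple(l.name for l in loci):
            raise ValidationError("all populations must share the same loci")
    codes = {locus.name: genepop_allele_codes(locus) for locus in loci}
    mapping = "; ".join(
        f"{locus.name}:" + ",".join(f"{a}={c}" for a, c in codes[locus.name].items())
        for locus in loci
    )
    path = Path(path)
    with path.open("w") as handle:
        handle.write((title or "breedauth export") + f" [allele codes {mapping}]\n")
        for locus in loci:
            handle.write(locus.name + "\n")
        for sample in samples:
            handle.write("Pop\n")
            for rec in sample.records:
                fields = []
                for locus in loci:
                    gt = rec.genotypes.get(locus.name)
                    if gt is None:
                        fields.append("0000")
                    else:
                        c = codes[locus.name]
                        fields.append(c[gt.alleles[0]] + c[gt.alleles[1]])
                handle.write(f"{sample.name}-{rec.animal_id} ,  " + " ".join(fields) + "\n")


def read_genepop(path, locus_defs: Sequence[Locus] = DEFAULT_LOCI) -> list[PopulationSample]:
    """Read a GENEPOP file written by :func:`write_genepop` (round-trip support).

    Locus names in the file must match ``locus_defs``; allele codes are
    decoded with the same lexicographic convention used on output.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GENEPOP file")
    locus_map = {locus.name: locus for locus in locus_defs}
    loci: list[Locus] = []
    idx = 1
    while idx < len(lines) and lines[idx].strip().lower() != "pop":
        names = [n.strip() for n in lines[idx].split(",") if n.strip()]
        for name in names:
            if name not in locus_map:
                raise FormatError(f"{path}: unknown locus {name!r}")
            loci.append(locus_map[name])
        idx += 1
    if not loci:
        raise FormatError(f"{path}: no locus lines before first Pop")
    decode = {
        locus.name: {code: a for a, code in genepop_allele_codes(locus).items()}
        for locus in loci
    }
    populations: list[PopulationSample] = []
    current: list[AnimalRecord] = []

    def flush() -> None:
        if current:
            populations.append(
                PopulationSample(
                    name=f"pop{len(populations) + 1}",
                    records=list(current),
                    loci=tuple(loci),
                )
            )
            current.clear()

    for line in lines[idx:]:
        text = line.strip()
        if not text:
            continue
        if text.lower() == "pop":
            flush()
            continue
        if "," not in text:
            raise FormatError(f"{path}: malformed individual line {text!r}")
        ident, geno = text.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise FormatError(f"{path}: expected {len(loci)} genotypes on {text!r}")
        genotypes: dict[str, Genotype] = {}
        for locus, f in zip(loci, fields):
            if len(f) != 4:
                raise FormatError(f"{path}: bad 4-digit code {f!r}")
            if f == "0000":
                continue
            a, b = f[:2], f[2:]
            try:
                genotypes[locus.name] = Genotype(locus, decode[locus.name][a], decode[locus.name][b])
            except KeyError as exc:
                raise FormatError(f"{path}: unknown allele code in {f!r}") from exc
        current.append(
            AnimalRecord(
                animal_id=ident.strip(),
                breed=f"pop{len(populations) + 1}",
                sex_class="sow",
                genotypes=genotypes,
            )
        )
    flush()
    return populations


def read_frequency_table(
    path,
    sep: str = ",",
    tolerance: float = AlleleFrequencyTable.READ_TOLERANCE,
    strict: bool = True,
) -> AlleleFrequencyTable:
    """Read a long-form ``breed,n,locus,allele,freq`` table.

    Sum-to-one is checked per breed/locus at ``tolerance`` (raises when
    ``strict``, otherwise collects warnings accessible via
    :meth:`AlleleFrequencyTable.validate`).
    """
    path = Path(path)
    entries: dict[str, dict[str, tuple[dict[str, Fraction | float], int]]] = defaultdict(dict)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter=sep)
        required = {"breed", "n", "locus", "allele", "freq"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: header must contain {sorted(required)}")
        for line_no, row in enumerate(reader, start=2):
            breed = row["breed"].strip()
            locus = row["locus"].strip()
            allele = row["allele"].strip()
            try:
                freq = float(row["freq"])
                n = int(row["n"])
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
            if not (0.0 <= freq <= 1.0):
                raise ValidationError(
                    f"{path}:{line_no}: frequency {freq} out of [0,1] "
                    f"({breed}/{locus}/{allele})"
                )
            freqs, _ = entries[breed].setdefault(locus, ({}, n))
            freqs[allele] = freq
            entries[breed][locus] = (freqs, n)
    table = AlleleFrequencyTable(entries=dict(entries))
    table.validate(tolerance=tolerance, strict=strict)
    return table


def write_frequency_table(table: AlleleFrequencyTable, path, sep: str = ",") -> None:
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=sep)
        writer.writerow(["breed", "n", "locus", "allele", "freq"])
        for breed, per_breed in table.entries.items():
            for locus, (freqs, n) in per_breed.items():
                for allele, freq in freqs.items():
                    writer.writerow([breed, n, locus, allele, f"{float(freq):.6g}"])
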