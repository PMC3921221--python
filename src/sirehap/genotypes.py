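"""Domain types for two-locus SSCP genotypes and the genotype-table format.

A "region" here is one of two typed stretches of a gene (e.g. exon 2-intron 2
and exon 3-intron 3 of ovine FABP4); an "allele" is an SSCP sequence variant
of one region, named by an opaque label such as ``A1`` or ``C2``.  Genotypes
are unordered pairs of same-region alleles; a paternal haplotype is the
ordered combination of one region-1 and one region-2 allele carried on the
chromosome a progeny inherited from its sire.

The on-disk format is a UTF-8 TSV with the header
``animal_id  sire_id  role  region1  region2``; genotypes are written
``X/Y`` with alleles in lexicographic order, missing genotypes as ``./.``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

MISSING = "./."

REGIONS = (1, 2)


class GenotypeTableError(ValueError):
    """Malformed or referentially inconsistent genotype table."""


@dataclass(frozen=True, order=True)
class Allele:
    """A sequence variant of one gene region, identified by label."""

    region: int
    label: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be 1 or 2, got {self.region!r}")
        if not self.label:
            raise ValueError("allele label must be non-empty")

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class LocusGenotype:
    """Unordered pair of alleles at one region (identical pair = homozygote).

    Equality ignores order: ``{A1,D1} == {D1,A1}``.  The canonical internal
    order (and the serialized order) is lexicographic by label.
    """

    region: int
    alleles: tuple[Allele, Allele]

    def __post_init__(self) -> None:
        a, b = self.alleles
        if a.region != self.region or b.region != self.region:
            raise ValueError(
                f"alleles {a.label}, {b.label} must belong to region {self.region}"
            )
        if b.label < a.label:
            object.__setattr__(self, "alleles", (b, a))

    @classmethod
    def from_labels(cls, region: int, a: str, b: str) -> "LocusGenotype":
        return cls(region, (Allele(region, a), Allele(region, b)))

    @property
    def labels(self) -> tuple[str, str]:
        return (self.alleles[0].label, self.alleles[1].label)

    @property
    def is_heterozygous(self) -> bool:
        return self.alleles[0] != self.alleles[1]

    def allele_set(self) -> frozenset[Allele]:
        return frozenset(self.alleles)

    def __contains__(self, allele: Allele) -> bool:
        return allele in self.alleles

    def __str__(self) -> str:
        return f"{self.alleles[0].label}/{self.alleles[1].label}"


@dataclass(frozen=True, order=True)
class PaternalHaplotype:
    """Ordered (region-1 allele, region-2 allele) pair transmitted by a sire."""

    region1_allele: Allele
    region2_allele: Allele

    def __post_init__(self) -> None:
        if self.region1_allele.region != 1 or self.region2_allele.region != 2:
            raise ValueError("haplotype must pair a region-1 with a region-2 allele")

    @classmethod
    def from_labels(cls, a1: str, a2: str) -> "PaternalHaplotype":
        return cls(Allele(1, a1), Allele(2, a2))

    @property
    def labels(self) -> tuple[str, str]:
        return (self.region1_allele.label, self.region2_allele.label)

    def __str__(self) -> str:
        return f"{self.region1_allele.label}-{self.region2_allele.label}"


@dataclass(frozen=True)
class AnimalRecord:
    """One row of the genotype table: a sire or a progeny with its genotypes."""

    animal_id: str
    role: str  # "sire" | "progeny"
    sire_id: Union[str, None] = None
    genotype1: Union[LocusGenotype, None] = None
    genotype2: Union[LocusGenotype, None] = None

    def __post_init__(self) -> None:
        if self.role not in ("sire", "progeny"):
            raise ValueError(f"role must be 'sire' or 'progeny', got {self.role!r}")
        if self.role == "progeny" and not self.sire_id:
            raise ValueError(f"progeny {self.animal_id!r} lacks a sire_id")

    def genotype(self, region: int) -> Union[LocusGenotype, None]:
        return self.genotype1 if region == 1 else self.genotype2


@dataclass
class FamilyDataset:
    """A set of sires plus their half-sib progeny, grouped by sire."""

    sires: dict[str, AnimalRecord] = field(default_factory=dict)
    progeny_by_sire: dict[str, list[AnimalRecord]] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[AnimalRecord]) -> "FamilyDataset":
        ds = cls()
        seen: set[str] = set()
        progeny: list[AnimalRecord] = []
        for rec in records:
            if rec.animal_id in seen:
                raise GenotypeTableError(f"duplicate animal_id {rec.animal_id!r}")
            seen.add(rec.animal_id)
            if rec.role == "sire":
                ds.sires[rec.animal_id] = rec
                ds.progeny_by_sire.setdefault(rec.animal_id, [])
            else:
                progeny.append(rec)
        for rec in progeny:
            if rec.sire_id not in ds.sires:
                raise GenotypeTableError(
                    f"progeny {rec.animal_id!r} references unknown sire {rec.sire_id!r}"
                )
            ds.progeny_by_sire[rec.sire_id].append(rec)
        return ds

    def progeny_of(self, sire_id: str) -> list[AnimalRecord]:
        if sire_id not in self.sires:
            raise KeyError(f"unknown sire {sire_id!r}")
        return self.progeny_by_sire[sire_id]

    @property
    def n_progeny(self) -> int:
        return sum(len(v) for v in self.progeny_by_sire.values())

    def records(self) -> list[AnimalRecord]:
        out: list[AnimalRecord] = []
        for sid in self.sires:
            out.append(self.sires[sid])
            out.extend(self.progeny_by_sire[sid])
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FamilyDataset):
            return NotImplemented
        return self.sires == other.sires and self.progeny_by_sire == other.progeny_by_sire


_HEADER = ["animal_id", "sire_id", "role", "region1", "region2"]


def _parse_genotype(text: str, region: int, line_no: int) -> Union[LocusGenotype, None]:
    if text == MISSING:
        return None
    parts = text.split("/")
    if len(parts) != 2 or not all(parts):
        raise GenotypeTableError(
            f"line {line_no}: malformed genotype {text!r} (expected 'X/Y' or './.')"
        )
    try:
        return LocusGenotype.from_labels(region, parts[0], parts[1])
    except ValueError as exc:
        raise GenotypeTableError(f"line {line_no}: {exc}") from exc


def read_genotype_table(path: Union[str, Path]) -> FamilyDataset:
    """Read and validate a genotype-table TSV into a :class:`FamilyDataset`.

    Raises :class:`GenotypeTableError` naming the offending line for malformed
    genotype strings, duplicate animal ids, or progeny whose ``sire_id`` does
    not resolve to a sire record in the same file.
    """
    records: list[AnimalRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeTableError(f"{path}: empty file") from None
        if header != _HEADER:
            raise GenotypeTableError(
                f"{path}: bad header {header!r}, expected {_HEADER!r}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 5:
                raise GenotypeTableError(
                    f"line {line_no}: expected 5 tab-separated fields, got {len(row)}"
                )
            animal_id, sire_id, role, g1, g2 = (f.strip() for f in row)
            try:
                records.append(
                    AnimalRecord(
                        animal_id=animal_id,
                        role=role,
                        sire_id=sire_id or None,
                        genotype1=_parse_genotype(g1, 1, line_no),
                        genotype2=_parse_genotype(g2, 2, line_no),
                    )
                )
            except GenotypeTableError:
                raise
            except ValueError as exc:
                raise GenotypeTableError(f"line {line_no}: {exc}") from exc
    return FamilyDataset.from_records(records)


def write_genotype_table(dataset: FamilyDataset, path: Union[str, Path]) -> None:
    """Write a dataset as a genotype-table TSV in canonical (lexicographic) form."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for rec in dataset.records():
            writer.writerow(
                [
                    rec.animal_id,
                    rec.sire_id or "",
                    rec.role,
                    str(rec.genotype1) if rec.genotype1 else MISSING,
                    str(rec.genotype2) if rec.genotype2 else MISSING,
                ]
            )
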