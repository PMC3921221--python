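"""Per-progeny inference of the allele transmitted by a doubly heterozygous sire.

In a half-sib design the dam genotypes are unknown, so the paternal allele at
a region can be deduced only from the sire/progeny genotype comparison:

* if exactly one of the sire's two alleles appears in the progeny genotype,
  that allele was transmitted (DETERMINED);
* if the progeny genotype equals the sire genotype (as a set), either sire
  allele could have been transmitted (AMBIGUOUS) — such progeny are excluded;
* if the progeny shares no allele with the sire, transmission is Mendelian-
  impossible (INCOMPATIBLE) and the progeny is flagged as putative
  non-paternity;
* a missing progeny genotype is UNDETERMINED.

A progeny is INFORMATIVE iff the transmitted allele is determined at both
regions; only then can the two-locus paternal haplotype be assembled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Union

from .genotypes import (
    Allele,
    AnimalRecord,
    FamilyDataset,
    LocusGenotype,
    PaternalHaplotype,
)


class SireNotHeterozygousError(ValueError):
    """The study design requires sires heterozygous at both typed regions."""


class TransmissionStatus(enum.Enum):
    DETERMINED = "determined"
    AMBIGUOUS = "ambiguous"
    INCOMPATIBLE = "incompatible"
    UNDETERMINED = "undetermined"


class OverallStatus(enum.Enum):
    INFORMATIVE = "informative"
    EXCLUDED_AMBIGUOUS = "excluded_ambiguous"
    FLAGGED_INCOMPATIBLE = "flagged_incompatible"
    EXCLUDED_MISSING = "excluded_missing"


@dataclass(frozen=True)
class TransmissionCall:
    """Outcome of paternal-allele deduction at one region."""

    status: TransmissionStatus
    allele: Union[Allele, None] = None

    def __post_init__(self) -> None:
        if (self.allele is not None) != (self.status is TransmissionStatus.DETERMINED):
            raise ValueError("allele is present iff status is DETERMINED")


@dataclass(frozen=True)
class ProgenyClassification:
    """Two per-region calls plus the assembled haplotype and overall status."""

    animal_id: str
    call1: TransmissionCall
    call2: TransmissionCall
    haplotype: Union[PaternalHaplotype, None]
    overall: OverallStatus


def infer_transmitted_allele(
    sire_genotype: LocusGenotype, progeny_genotype: Union[LocusGenotype, None]
) -> TransmissionCall:
    """Deduce which sire allele a progeny inherited at one region.

    ``sire_genotype`` must be heterozygous; a homozygous sire is a hard error
    because no transmission is deducible from an uninformative parent.
    """
    if not sire_genotype.is_heterozygous:
        raise SireNotHeterozygousError(
            f"sire is homozygous {sire_genotype} at region {sire_genotype.region}"
        )
    if progeny_genotype is None:
        return TransmissionCall(TransmissionStatus.UNDETERMINED)
    if progeny_genotype.region != sire_genotype.region:
        raise ValueError(
            f"region mismatch: sire region {sire_genotype.region}, "
            f"progeny region {progeny_genotype.region}"
        )
    sire_set = sire_genotype.allele_set()
    prog_set = progeny_genotype.allele_set()
    if prog_set == sire_set:
        return TransmissionCall(TransmissionStatus.AMBIGUOUS)
    shared = sire_set & prog_set
    if len(shared) == 1:
        return TransmissionCall(TransmissionStatus.DETERMINED, next(iter(shared)))
    # len(shared) == 2 would force prog_set == sire_set (both are <=2-sets),
    # already handled above; so here the progeny shares no sire allele.
    return TransmissionCall(TransmissionStatus.INCOMPATIBLE)


def _overall(call1: TransmissionCall, call2: TransmissionCall) -> OverallStatus:
    statuses = {call1.status, call2.status}
    if TransmissionStatus.INCOMPATIBLE in statuses:
        return OverallStatus.FLAGGED_INCOMPATIBLE
    if TransmissionStatus.AMBIGUOUS in statuses:
        return OverallStatus.EXCLUDED_AMBIGUOUS
    if TransmissionStatus.UNDETERMINED in statuses:
        return OverallStatus.EXCLUDED_MISSING
    return OverallStatus.INFORMATIVE


def classify_progeny(sire: AnimalRecord, progeny: AnimalRecord) -> ProgenyClassification:
    """Classify one progeny against its sire at both regions."""
    if sire.genotype1 is None or sire.genotype2 is None:
        raise ValueError(f"sire {sire.animal_id!r} has a missing genotype")
    call1 = infer_transmitted_allele(sire.genotype1, progeny.genotype1)
    call2 = infer_transmitted_allele(sire.genotype2, progeny.genotype2)
    overall = _overall(call1, call2)
    haplotype = None
    if overall is OverallStatus.INFORMATIVE:
        assert call1.allele is not None and call2.allele is not None
        haplotype = PaternalHaplotype(call1.allele, call2.allele)
    return ProgenyClassification(
        animal_id=progeny.animal_id,
        call1=call1,
        call2=call2,
        haplotype=haplotype,
        overall=overall,
    )


def classify_family(dataset: FamilyDataset, sire_id: str) -> list[ProgenyClassification]:
    """Classify every progeny of one sire; the result has one entry per progeny."""
    sire = dataset.sires.get(sire_id)
    if sire is None:
        raise KeyError(f"unknown sire {sire_id!r}")
    return [classify_progeny(sire, prog) for prog in dataset.progeny_of(sire_id)]
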