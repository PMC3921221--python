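"""Deterministic reconstruction of the seven-sire ovine FABP4 half-sib study.

The published sire-line summary reports, for each of seven doubly
heterozygous NZ Romney sires, the two-locus genotype, the total progeny
count, and the count of informative progeny per observed paternal haplotype.
:func:`make_table1_fixture` rebuilds a 420-progeny genotype table consistent
with those tallies: each informative progeny pairs its paternal haplotype's
alleles with a maternal allele chosen outside the sire's genotype (so the
paternal allele is forced at both regions), and the remaining progeny
duplicate the sire's genotype at both regions (so they are excluded as
sire-identical).  The reconstruction is byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genotypes import AnimalRecord, FamilyDataset, LocusGenotype, PaternalHaplotype

REGION1_ALPHABET = ("A1", "B1", "C1", "D1", "E1")
REGION2_ALPHABET = ("A2", "B2", "C2", "D2")


@dataclass(frozen=True)
class SireLine:
    sire_id: str
    region1: tuple[str, str]
    region2: tuple[str, str]
    total_progeny: int
    haplotype_counts: tuple[tuple[str, str, int], ...]  # (r1 allele, r2 allele, n)

    @property
    def n_informative(self) -> int:
        return sum(n for *_, n in self.haplotype_counts)


# Published per-sire tallies: 420 progeny, 232 informative, 11 recombinants.
STUDY_SIRE_LINES: tuple[SireLine, ...] = (
    SireLine("Totaranui_376_02", ("A1", "D1"), ("A2", "B2"), 67,
             (("A1", "B2", 23), ("D1", "A2", 17))),
    SireLine("Waidale_618_04", ("C1", "D1"), ("A2", "C2"), 68,
             (("C1", "C2", 22), ("D1", "A2", 24), ("C1", "A2", 1))),
    SireLine("Snowlea_192_02", ("B1", "C1"), ("B2", "C2"), 65,
             (("B1", "B2", 16), ("C1", "C2", 18), ("C1", "B2", 1))),
    SireLine("Mana_83_04", ("B1", "C1"), ("B2", "C2"), 62,
             (("B1", "B2", 17), ("C1", "C2", 13), ("C1", "B2", 1))),
    SireLine("Doughboy_45_04", ("B1", "C1"), ("A2", "B2"), 69,
             (("B1", "B2", 22), ("C1", "A2", 16), ("C1", "B2", 4))),
    SireLine("Glenleith_25_02", ("A1", "B1"), ("A2", "B2"), 42,
             (("A1", "A2", 11), ("B1", "B2", 7), ("B1", "A2", 1))),
    SireLine("Mana_90_01", ("A1", "C1"), ("A2", "B2"), 47,
             (("A1", "B2", 8), ("C1", "A2", 7), ("A1", "A2", 2), ("C1", "B2", 1))),
)


def _non_sire_allele(sire_alleles: tuple[str, str], alphabet: tuple[str, ...]) -> str:
    """Lexicographically first allele outside the sire's genotype."""
    for label in alphabet:
        if label not in sire_alleles:
            return label
    raise RuntimeError("allele alphabet exhausted")  # 5 (resp. 4) labels vs 2 used


def make_table1_fixture() -> FamilyDataset:
    """Build the deterministic 420-progeny study dataset described above."""
    records: list[AnimalRecord] = []
    for line in STUDY_SIRE_LINES:
        sire_g1 = LocusGenotype.from_labels(1, *line.region1)
        sire_g2 = LocusGenotype.from_labels(2, *line.region2)
        records.append(
            AnimalRecord(
                animal_id=line.sire_id, role="sire",
                genotype1=sire_g1, genotype2=sire_g2,
            )
        )
        m1 = _non_sire_allele(line.region1, REGION1_ALPHABET)
        m2 = _non_sire_allele(line.region2, REGION2_ALPHABET)
        idx = 0
        for a1, a2, n in line.haplotype_counts:
            for _ in range(n):
                idx += 1
                records.append(
                    AnimalRecord(
                        animal_id=f"{line.sire_id}_L{idx:03d}",
                        role="progeny",
                        sire_id=line.sire_id,
                        genotype1=LocusGenotype.from_labels(1, a1, m1),
                        genotype2=LocusGenotype.from_labels(2, a2, m2),
                    )
                )
        for _ in range(line.total_progeny - line.n_informative):
            idx += 1
            records.append(
                AnimalRecord(
                    animal_id=f"{line.sire_id}_L{idx:03d}",
                    role="progeny",
                    sire_id=line.sire_id,
                    genotype1=sire_g1,
                    genotype2=sire_g2,
                )
            )
    return FamilyDataset.from_records(records)


def study_haplotype_counts() -> dict[str, dict[PaternalHaplotype, int]]:
    """The published per-sire haplotype tallies, keyed by sire id."""
    return {
        line.sire_id: {
            PaternalHaplotype.from_labels(a1, a2): n
            for a1, a2, n in line.haplotype_counts
        }
        for line in STUDY_SIRE_LINES
    }
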