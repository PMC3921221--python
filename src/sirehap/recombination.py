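"""Family-level haplotype counting, recombinant detection and rate estimation.

A sire heterozygous X1/Y1 at region 1 and X2/Y2 at region 2 carries one of
two possible phase configurations: {X1-X2, Y1-Y2} or {X1-Y2, Y1-X2}.  These
"complementary" pairs partition the 2x2 cross of the sire's alleles; the two
haplotypes outside the sire's phase are the crossover products.  The phase is
identified from the progeny as the complementary pair with the greatest
summed count (the two common haplotypes); informative progeny carrying a
haplotype outside that pair are recombinants.

The pooled recombination rate is the simple ratio of recombinant haplotypes
to informative progeny across families, with a 95% Wilson score interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from io import StringIO
from typing import Iterable, Mapping, Union

from statsmodels.stats.proportion import proportion_confint

from .genotypes import AnimalRecord, LocusGenotype, PaternalHaplotype
from .inference import OverallStatus, ProgenyClassification


class IndeterminatePhaseError(ValueError):
    """The two complementary pairs tie in summed count; phase cannot be assigned."""


class InconsistentHaplotypeError(ValueError):
    """A counted haplotype uses an allele absent from the sire's genotypes."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (school rounding), not banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def complementary_pairs(
    region1: LocusGenotype, region2: LocusGenotype
) -> tuple[frozenset[PaternalHaplotype], frozenset[PaternalHaplotype]]:
    """The two possible phase configurations of a doubly heterozygous sire."""
    x1, y1 = region1.alleles
    x2, y2 = region2.alleles
    cis = frozenset({PaternalHaplotype(x1, x2), PaternalHaplotype(y1, y2)})
    trans = frozenset({PaternalHaplotype(x1, y2), PaternalHaplotype(y1, x2)})
    return cis, trans


def crossover_products(
    parental_pair: frozenset[PaternalHaplotype],
) -> frozenset[PaternalHaplotype]:
    """The (at most two) single-crossover products of a parental pair."""
    h1, h2 = sorted(parental_pair)
    return frozenset(
        {
            PaternalHaplotype(h1.region1_allele, h2.region2_allele),
            PaternalHaplotype(h2.region1_allele, h1.region2_allele),
        }
    )


def identify_parental_pair(
    counts: Mapping[PaternalHaplotype, int],
    sire_genotypes: tuple[LocusGenotype, LocusGenotype],
) -> frozenset[PaternalHaplotype]:
    """Pick the complementary pair with the greatest summed observed count.

    Both members of the winning pair need not be observed; a family may show
    one parental haplotype plus recombinants.  An exact tie between the two
    pairs raises :class:`IndeterminatePhaseError` rather than guessing.
    """
    if not counts:
        raise ValueError("empty haplotype counts")
    region1, region2 = sire_genotypes
    cis, trans = complementary_pairs(region1, region2)
    valid = cis | trans
    for hap in counts:
        if hap not in valid:
            raise InconsistentHaplotypeError(
                f"haplotype {hap} is not constructible from sire genotypes "
                f"{region1} x {region2}"
            )
    cis_total = sum(counts.get(h, 0) for h in cis)
    trans_total = sum(counts.get(h, 0) for h in trans)
    if cis_total == trans_total:
        raise IndeterminatePhaseError(
            f"complementary pairs tie at {cis_total} observations each"
        )
    return cis if cis_total > trans_total else trans


@dataclass
class FamilyResult:
    """Per-sire haplotype tallies, identified phase and recombinants."""

    sire_id: str
    region1_genotype: LocusGenotype
    region2_genotype: LocusGenotype
    total_progeny: int
    n_informative: int
    haplotype_counts: dict[PaternalHaplotype, int]
    parental_pair: frozenset[PaternalHaplotype]
    recombinants: dict[PaternalHaplotype, int] = field(default_factory=dict)

    @property
    def n_recombinant(self) -> int:
        return sum(self.recombinants.values())

    @property
    def frequencies(self) -> dict[PaternalHaplotype, float]:
        """Percentage of informative progeny per haplotype, 1 decimal."""
        return {
            h: round_half_up(100.0 * c / self.n_informative)
            for h, c in self.haplotype_counts.items()
        }


def summarize_family(
    classifications: Iterable[ProgenyClassification], sire: AnimalRecord
) -> FamilyResult:
    """Tally informative progeny of one family and classify recombinants."""
    if sire.genotype1 is None or sire.genotype2 is None:
        raise ValueError(f"sire {sire.animal_id!r} has a missing genotype")
    classifications = list(classifications)
    counts: dict[PaternalHaplotype, int] = {}
    for cls in classifications:
        if cls.overall is OverallStatus.INFORMATIVE:
            assert cls.haplotype is not None
            counts[cls.haplotype] = counts.get(cls.haplotype, 0) + 1
    pair = identify_parental_pair(counts, (sire.genotype1, sire.genotype2))
    recomb = {h: c for h, c in counts.items() if h not in pair}
    return FamilyResult(
        sire_id=sire.animal_id,
        region1_genotype=sire.genotype1,
        region2_genotype=sire.genotype2,
        total_progeny=len(classifications),
        n_informative=sum(counts.values()),
        haplotype_counts=counts,
        parental_pair=pair,
        recombinants=recomb,
    )


@dataclass(frozen=True)
class PooledRate:
    """Recombination-fraction estimate pooled over families, with 95% Wilson CI."""

    n_recombinant: int
    n_informative: int
    rate: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.rate)

    def percent_str(self) -> str:
        return f"{self.percent:.1f}%"

    def fraction_str(self) -> str:
        return f"{self.n_recombinant}/{self.n_informative}"


def pooled_rate(results: Iterable[FamilyResult]) -> PooledRate:
    """Pool recombinant and informative counts across families into one rate."""
    results = list(results)
    if not results:
        raise ValueError("no family results to pool")
    n_rec = sum(r.n_recombinant for r in results)
    n_inf = sum(r.n_informative for r in results)
    if n_inf == 0:
        raise ValueError("no informative progeny in any family")
    low, high = proportion_confint(n_rec, n_inf, alpha=0.05, method="wilson")
    return PooledRate(
        n_recombinant=n_rec,
        n_informative=n_inf,
        rate=n_rec / n_inf,
        ci_low=float(low),
        ci_high=float(high),
    )


def analyze_dataset(
    dataset,
) -> tuple[dict[str, list[ProgenyClassification]], list["FamilyResult"], PooledRate]:
    """Run the full pipeline over every sire-line of a dataset.

    Returns per-sire progeny classifications, per-sire family results and the
    pooled recombination rate.
    """
    from .inference import classify_family

    classifications: dict[str, list[ProgenyClassification]] = {}
    results: list[FamilyResult] = []
    for sire_id in dataset.sires:
        cls = classify_family(dataset, sire_id)
        classifications[sire_id] = cls
        results.append(summarize_family(cls, dataset.sires[sire_id]))
    return classifications, results, pooled_rate(results)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

FAMILY_TSV_HEADER = [
    "sire_id",
    "region1_genotype",
    "region2_genotype",
    "total_progeny",
    "haplotype",
    "count",
    "frequency_pct",
    "is_recombinant",
]

POOLED_TSV_HEADER = ["n_recombinant", "n_informative", "rate", "ci_low", "ci_high"]


def _sorted_rows(result: FamilyResult) -> list[tuple[PaternalHaplotype, int, bool]]:
    # parental haplotypes first (by descending count), then recombinants
    parental = [
        (h, c, False) for h, c in result.haplotype_counts.items()
        if h in result.parental_pair
    ]
    recomb = [(h, c, True) for h, c in result.recombinants.items()]
    key = lambda row: (-row[1], str(row[0]))
    return sorted(parental, key=key) + sorted(recomb, key=key)


@dataclass(frozen=True)
class Report:
    """Per-sire table plus pooled summary, as TSV strings and readable text."""

    family_tsv: str
    pooled_tsv: str
    text: str


def report(results: Iterable[FamilyResult], pooled: PooledRate) -> Report:
    """Render per-sire tallies ("count (freq%)") and the pooled rate."""
    results = list(results)

    tsv = StringIO()
    tsv.write("\t".join(FAMILY_TSV_HEADER) + "\n")
    for res in results:
        freqs = res.frequencies
        for hap, count, is_rec in _sorted_rows(res):
            tsv.write(
                "\t".join(
                    [
                        res.sire_id,
                        str(res.region1_genotype),
                        str(res.region2_genotype),
                        str(res.total_progeny),
                        str(hap),
                        str(count),
                        f"{freqs[hap]:.1f}",
                        "yes" if is_rec else "no",
                    ]
                )
                + "\n"
            )

    pooled_tsv = (
        "\t".join(POOLED_TSV_HEADER)
        + "\n"
        + "\t".join(
            [
                str(pooled.n_recombinant),
                str(pooled.n_informative),
                f"{pooled.rate:.6f}",
                f"{pooled.ci_low:.6f}",
                f"{pooled.ci_high:.6f}",
            ]
        )
        + "\n"
    )

    text = StringIO()
    text.write("Paternal haplotypes detected in individual sire-lines\n")
    text.write("=" * 54 + "\n")
    for res in results:
        freqs = res.frequencies
        text.write(
            f"\nSire {res.sire_id}  "
            f"[{res.region1_genotype}; {res.region2_genotype}]  "
            f"{res.total_progeny} progeny, {res.n_informative} informative\n"
        )
        for hap, count, is_rec in _sorted_rows(res):
            marker = " *" if is_rec else ""
            text.write(f"  {str(hap):<8s} {count} ({freqs[hap]:.1f}%){marker}\n")
        if res.recombinants:
            text.write("  * recombined minor sire haplotype\n")
    text.write(
        f"\nPooled recombination rate: {pooled.fraction_str()} = "
        f"{pooled.percent_str()} "
        f"(95% CI {100 * pooled.ci_low:.1f}%-{100 * pooled.ci_high:.1f}%)\n"
    )
    return Report(family_tsv=tsv.getvalue(), pooled_tsv=pooled_tsv, text=text.getvalue())
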