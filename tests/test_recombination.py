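"""Parental-pair identification, family summaries, pooled rate and reporting."""

import math

import pytest

from sirehap import (
    AnimalRecord,
    FamilyResult,
    IndeterminatePhaseError,
    LocusGenotype,
    PaternalHaplotype,
    analyze_dataset,
    crossover_products,
    identify_parental_pair,
    pooled_rate,
    report,
    round_half_up,
    summarize_family,
)
from sirehap.inference import classify_family
from sirehap.recombination import InconsistentHaplotypeError

H = PaternalHaplotype.from_labels
G1 = lambda a, b: LocusGenotype.from_labels(1, a, b)
G2 = lambda a, b: LocusGenotype.from_labels(2, a, b)


def wilson_oracle(k, n, z=1.959963984540054):
    """Textbook Wilson score interval, coded independently of the package."""
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half


class TestIdentifyParentalPair:
    def test_two_haplotype_family(self):
        pair = identify_parental_pair(
            {H("A1", "B2"): 23, H("D1", "A2"): 17},
            (G1("A1", "D1"), G2("A2", "B2")),
        )
        assert pair == frozenset({H("A1", "B2"), H("D1", "A2")})

    def test_crossover_product_does_not_join_pair(self):
        pair = identify_parental_pair(
            {H("B1", "B2"): 22, H("C1", "A2"): 16, H("C1", "B2"): 4},
            (G1("B1", "C1"), G2("A2", "B2")),
        )
        assert pair == frozenset({H("B1", "B2"), H("C1", "A2")})
        assert H("C1", "B2") in crossover_products(pair)

    def test_perfect_tie_is_indeterminate(self):
        counts = {H("B1", "B2"): 5, H("C1", "A2"): 5, H("B1", "A2"): 5, H("C1", "B2"): 5}
        with pytest.raises(IndeterminatePhaseError):
            identify_parental_pair(counts, (G1("B1", "C1"), G2("A2", "B2")))

    def test_haplotype_outside_sire_cross_rejected(self):
        with pytest.raises(InconsistentHaplotypeError):
            identify_parental_pair(
                {H("E1", "B2"): 3}, (G1("B1", "C1"), G2("A2", "B2"))
            )

    def test_pair_identified_even_if_one_member_unobserved(self):
        pair = identify_parental_pair(
            {H("B1", "B2"): 10, H("C1", "B2"): 1},
            (G1("B1", "C1"), G2("A2", "B2")),
        )
        assert pair == frozenset({H("B1", "B2"), H("C1", "A2")})


def family_from_counts(sire_g1, sire_g2, counts, n_excluded=0, sire_id="S1"):
    """Build classifications realising given haplotype counts plus excluded progeny."""
    sire = AnimalRecord("S1", "sire", genotype1=sire_g1, genotype2=sire_g2)
    records = [sire]
    i = 0
    for hap, n in counts.items():
        for _ in range(n):
            i += 1
            records.append(
                AnimalRecord(
                    f"L{i}", "progeny", sire_id="S1",
                    genotype1=G1(hap.region1_allele.label, "E1"),
                    genotype2=G2(hap.region2_allele.label, "D2")
                    if "D2" not in {a.label for a in sire_g2.alleles}
                    else G2(hap.region2_allele.label, "C2"),
                )
            )
    for _ in range(n_excluded):
        i += 1
        records.append(
            AnimalRecord(f"L{i}", "progeny", sire_id="S1",
                         genotype1=sire_g1, genotype2=sire_g2)
        )
    from sirehap import FamilyDataset

    ds = FamilyDataset.from_records(records)
    return classify_family(ds, "S1"), sire


class TestSummarizeFamily:
    def test_three_haplotype_family_frequencies_and_recombinants(self):
        cls, sire = family_from_counts(
            G1("B1", "C1"), G2("A2", "B2"),
            {H("B1", "B2"): 22, H("C1", "A2"): 16, H("C1", "B2"): 4},
        )
        res = summarize_family(cls, sire)
        assert res.n_informative == 42
        assert res.frequencies[H("B1", "B2")] == 52.4
        assert res.frequencies[H("C1", "A2")] == 38.1
        assert res.frequencies[H("C1", "B2")] == 9.5
        assert res.recombinants == {H("C1", "B2"): 4}

    def test_two_recombinant_haplotypes_in_one_family(self):
        cls, sire = family_from_counts(
            G1("A1", "C1"), G2("A2", "B2"),
            {H("A1", "B2"): 8, H("C1", "A2"): 7, H("A1", "A2"): 2, H("C1", "B2"): 1},
        )
        res = summarize_family(cls, sire)
        assert res.parental_pair == frozenset({H("A1", "B2"), H("C1", "A2")})
        assert res.n_recombinant == 3
        assert len(res.recombinants) == 2

    def test_zero_recombinant_family(self):
        cls, sire = family_from_counts(
            G1("A1", "D1"), G2("A2", "B2"),
            {H("A1", "B2"): 23, H("D1", "A2"): 17},
        )
        res = summarize_family(cls, sire)
        assert res.recombinants == {}
        assert sum(res.frequencies.values()) == 100.0

    def test_counts_sum_to_informative_and_excluded_not_counted(self):
        cls, sire = family_from_counts(
            G1("A1", "D1"), G2("A2", "B2"),
            {H("A1", "B2"): 5, H("D1", "A2"): 3},
            n_excluded=4,
        )
        res = summarize_family(cls, sire)
        assert res.total_progeny == 12
        assert res.n_informative == 8
        assert sum(res.haplotype_counts.values()) == 8


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(9.52, 9.5), (11.111, 11.1), (4.741, 4.7), (57.5, 57.5), (2.25, 2.3),
         (38.095, 38.1)],
    )
    def test_half_away_from_zero_to_one_decimal(self, value, expected):
        assert round_half_up(value) == expected


class TestPooledRate:
    def test_study_fixture_pools_to_11_of_232(self, study_analysis):
        _, _, pooled = study_analysis
        assert pooled.n_recombinant == 11
        assert pooled.n_informative == 232
        assert pooled.percent_str() == "4.7%"

    def test_zero_recombinants_boundary(self):
        res = FamilyResult(
            sire_id="S1",
            region1_genotype=G1("A1", "D1"),
            region2_genotype=G2("A2", "B2"),
            total_progeny=40, n_informative=40,
            haplotype_counts={H("A1", "B2"): 20, H("D1", "A2"): 20},
            parental_pair=frozenset({H("A1", "B2"), H("D1", "A2")}),
        )
        pooled = pooled_rate([res])
        assert pooled.rate == 0.0
        assert pooled.ci_low == 0.0

    def test_wilson_interval_matches_independent_formula(self):
        res = FamilyResult(
            sire_id="S1",
            region1_genotype=G1("A1", "D1"),
            region2_genotype=G2("A2", "B2"),
            total_progeny=100, n_informative=100,
            haplotype_counts={H("A1", "B2"): 50, H("D1", "A2"): 45, H("A1", "A2"): 5},
            parental_pair=frozenset({H("A1", "B2"), H("D1", "A2")}),
            recombinants={H("A1", "A2"): 5},
        )
        pooled = pooled_rate([res])
        lo, hi = wilson_oracle(5, 100)
        assert pooled.rate == 0.05
        assert pooled.ci_low == pytest.approx(lo, abs=1e-9)
        assert pooled.ci_high == pytest.approx(hi, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pooled_rate([])


class TestReport:
    def test_cells_render_count_and_frequency(self, study_analysis):
        _, results, pooled = study_analysis
        rep = report(results, pooled)
        assert "Totaranui_376_02" in rep.text
        assert "23 (57.5%)" in rep.text
        assert "4 (9.5%)" in rep.text

    def test_pooled_section_renders_fraction_and_percent(self, study_analysis):
        _, results, pooled = study_analysis
        rep = report(results, pooled)
        assert "11/232" in rep.text
        assert "4.7%" in rep.text
        assert rep.pooled_tsv.splitlines()[1].startswith("11\t232\t")

    def test_family_tsv_flags_recombinants(self, study_analysis):
        _, results, pooled = study_analysis
        rep = report(results, pooled)
        rec_rows = [l for l in rep.family_tsv.splitlines() if l.endswith("\tyes")]
        assert sum(int(r.split("\t")[5]) for r in rec_rows) == 11

    def test_no_recombinant_marker_for_clean_family(self):
        cls, sire = family_from_counts(
            G1("A1", "D1"), G2("A2", "B2"),
            {H("A1", "B2"): 3, H("D1", "A2"): 2},
        )
        res = summarize_family(cls, sire)
        rep = report([res], pooled_rate([res]))
        assert "*" not in rep.text.split("Pooled")[0]


class TestAnalyzeDatasetInvariants:
    def test_at_most_four_haplotypes_and_counts_conserved(self, study_analysis):
        _, results, _ = study_analysis
        for res in results:
            assert len(res.haplotype_counts) <= 4
            assert sum(res.haplotype_counts.values()) == res.n_informative
            for hap in res.recombinants:
                assert hap in crossover_products(res.parental_pair)
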