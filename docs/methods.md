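# Methods

## Inference model

The design is a half-sib progeny test: each family shares one sire,
heterozygous at both typed gene regions, and dams are unobserved.  At one
region with sire genotype {X, Y} and progeny genotype *P* (an unordered
pair), the transmitted paternal allele is found by set comparison:

- exactly one of X, Y in *P* → DETERMINED (this covers progeny homozygous
  for a sire allele — the dam then contributed the same allele — and
  heterozygous progeny with one non-sire allele);
- *P* = {X, Y} → AMBIGUOUS;
- no shared allele → INCOMPATIBLE.

This rule is provably equivalent to enumerating all (paternal allele, dam
allele) combinations and asking which paternal alleles are consistent with
*P*; the test suite checks that equivalence exhaustively over a five-allele
region.  A homozygous sire is a hard error, not a degraded mode: the design
selects double heterozygotes, and nothing is inferable from a homozygous
parent.

A progeny is INFORMATIVE iff both regions are DETERMINED; only then is the
two-locus paternal haplotype assembled.  When exclusion reasons co-occur
the precedence is INCOMPATIBLE > AMBIGUOUS > MISSING: incompatibility is
evidence about pedigree integrity and must not be hidden by an ambiguity at
the other region; ambiguity in observed data is reported ahead of
missingness because it is a property of the comparison, not of data
collection.  Incompatible progeny (putative non-paternity) are excluded
from both the numerator and denominator of the rate estimate.  Missing
genotypes (`./.`) are accepted on input and excluded as EXCLUDED_MISSING;
the motivating study had none, but real SSCP datasets do.

## Phase identification and recombinants

A sire heterozygous X1/Y1 and X2/Y2 admits exactly two phase
configurations, the complementary pairs {X1-X2, Y1-Y2} and {X1-Y2, Y1-X2}.
The observed phase is the pair with the greater summed count among
informative progeny — the two common haplotypes; both members need not be
observed.  An exact tie raises an IndeterminatePhaseError rather than
picking arbitrarily, since every downstream recombinant call depends on the
phase.  Informative haplotypes outside the identified pair are recombinants;
by construction they lie in the crossover set of the parental pair, and at
most four distinct haplotypes (the 2×2 allele cross) can occur.

The pooled rate is the simple ratio Σ recombinants / Σ informative across
families — no per-sire random effect is fitted.  Its 95% interval is the
Wilson score interval (via statsmodels), preferred over the Wald interval
because the estimate is a small proportion where Wald undercovers.

Exclusion of sire-identical progeny does not bias the estimate: the
maternal contribution is independent of the transmitted paternal gamete, so
the event "progeny is ambiguous" is independent of the event "gamete is
recombinant".  This conditioning argument is verified by simulation (see
below) rather than assumed.

Percentages are rounded half away from zero to one decimal; this
reproduces every frequency in the motivating study's sire-line table
(e.g. 9.52 → 9.5, 11.11 → 11.1, 4.74 → 4.7), where banker's rounding
would not.

## Motif scanner

The built-in catalogue holds the hotspot-associated motifs: chi
(`GCTGGTGG`), CRE/M26 (`ATGACGTCA`), `CCTCCCT` and `CCAAT` as exact
classes, plus "chi-like", "CRE-like" and "CCTCCCT-variant" classes defined
as Hamming distance exactly 1 from the consensus.  Distance 1 is a design
choice: the named variants in the hotspot literature (GCTGGTGC, GCTGGTGA,
ATGAAGTCA) are all single substitutions, and admitting indels would change
the window geometry.  Exact matches are excluded from the variant classes
so the two never double count.  CCTCCCT variants with C at position 3 are
annotated `suppressor` (the known hotspot-suppressing T→C change).

Both strands are scanned by default.  All output coordinates are 1-based
inclusive on the forward sequence; a minus-strand hit carries the forward
start of its window and its matched text as read 5′→3′ on the minus strand.
The BED-like TSV uses 0-based half-open starts, as BED does.  Windows
containing `N` yield no hit in any class — counting `N` as an affordable
mismatch would let masked sequence surface as spurious "variants".
Overlap events pair same-family, same-strand hits with intersecting
windows; the reported span is the intersection.

## Simulator

The simulator emulates the study design: each sire is specified by its two
parental haplotypes; a gamete is parental (equiprobably H1 or H2) with
probability 1 − r and one of the two crossover products (equiprobably)
with probability r.  r ∈ [0, 0.5] is a direct Bernoulli probability per
meiosis — a single-crossover model, not a map distance.  Each progeny
genotype unions the paternal allele with an independent maternal draw per
region from configured allele frequencies; maternal haplotype structure
(LD) is not modelled because dams are unobservable in this design and
maternal LD affects only ambiguity rates, not the correctness of paternal
inference.  Every draw is written to a truth log so inference can be
checked exactly.  Randomness comes from a `numpy` Generator seeded
explicitly in the config; there is no global state.

The default study template mirrors the motivating design: 7 doubly
heterozygous sires × 60 progeny, 5 region-1 and 4 region-2 variants with
even maternal frequencies (0.2 / 0.25).  Even frequencies are a neutral
choice: the study reports no maternal frequencies, and its observed 44.8%
exclusion fraction constrains but does not determine them (the template
gives 1 − 0.8 × 0.75 = 40%).

Useful closed forms under this model, used as test oracles:

- P(ambiguous at region i) = (f(Xi) + f(Yi)) / 2, where f are maternal
  frequencies of the sire's alleles;
- P(excluded) = 1 − (1 − q1)(1 − q2) with qi as above (ambiguity is
  independent across regions given independent maternal draws);
- the pooled estimate over informative progeny is unbiased for r.

## What the tests do and do not show

The deterministic seven-sire fixture reconstructs the published sire-line
tallies exactly: informative progeny pair their paternal haplotype's
alleles with a maternal allele outside the sire's genotype, and the
remaining progeny duplicate the sire genotype at both regions.  The study
reported exclusion at "either one or both regions" without a breakdown, so
the both-regions reconstruction is the simplest consistent one; no pooled
or per-family acceptance number depends on that choice.  Pipeline runs on
this fixture reproduce every published count and frequency cell, the
232/188 informative/excluded split, and the pooled 11/232 = 4.7%.

Simulation-based tests run at these sizes, chosen to keep Monte-Carlo error
well below the tested margins: single families of n = 5000 for
rate recovery at r ∈ {0.01, 0.05, 0.2} and for the exclusion closed form
(3-standard-error bands), and 200 seeded replicates of the 7 × 60 template
for Wilson-interval coverage (≥ 93% observed at nominal 95%).

Passing on simulated data shows the pipeline is correct under its own
model: error-free genotyping, correct pedigrees, single crossovers,
independent maternal draws.  Real SSCP data can violate all four (typing
error, mis-assigned sires, gene conversion or double crossovers mimicking
or hiding recombinants); the pipeline flags Mendelian incompatibilities but
does not model genotyping error, and minor haplotypes produced by gene
conversion are indistinguishable from crossovers at two loci.

## Known limitations

- Ambiguous progeny are excluded, not integrated out; a likelihood treatment
  could recover part of that information but is out of scope.
- The pooled estimate assumes a common r across sires; no heterogeneity
  test or per-sire random effect is provided.
- Motif "variants" are substitution-only (Hamming 1); no PWM or enrichment
  statistics — presence/position reporting only.
- Phase identification assumes recombinants are the minority; at r near
  0.5 or in tiny families the maximal-count rule can misassign phase, and
  ties abort with an explicit error.
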