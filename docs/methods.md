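# Methods

This note documents the models behind `cryptomap`, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
conventions used throughout.

## Cross and meiosis model

Segregants are haploid gametes of a cross between a trait-expressing
("rough") recombinant and a pure recurrent parent (BY or 3S). Genotypes are
binary per marker (0 = BY/P1, 1 = 3S/P2, −1 = missing). Meiosis assumes a
Poisson crossover process with no interference, i.e. the Haldane map
function: between adjacent markers separated by *d* Morgans the parental
state switches with probability r = ½(1 − e^(−2d)), which is exactly the
probability of an odd Poisson crossover count, so switches are sampled
directly at marker resolution rather than materializing crossover events.
Chromosomes assort independently from a fair starting parent.

The default recombination rate is **3×10⁻⁶ Morgans/bp** (≈0.3 cM/kb, the
order of the yeast genome-wide average; ~3 expected crossovers on a 1-Mb test
chromosome). It is a conventional default, not inferred from data, and is
configurable everywhere it enters (simulation and HMM transitions).

Trait-expressing founder haplotypes (`make_rough_parent`) are F2-like
gametes conditioned on carrying the alleles the trait model requires.
Conditioning flips the entire contiguous same-parent block containing a
required locus: a lone single-marker island would be a haplotype no real
meiosis produces and would make the locus invisible to linkage-based
genotyping.

## Trait models

Two modes realize the two genetic architectures observed for this class of
trait:

* **rule_based** — a set of AND-rules, each a required multi-locus allele
  combination with a maximal expression temperature in {21, 30, 37}. A
  segregant is rough at temperature T iff some rule with max_temperature ≥ T
  is satisfied; expression is therefore deterministic and monotone in
  temperature, giving the three temperature-sensitivity classes (rough at
  21° only, up to 30°, up to 37°). Multiple rules produce genotypic
  heterogeneity: distinct allele combinations among selected segregants.
* **multiplicative** — the trait is expressed at 21 °C only, with
  probability min(1, baseline·∏ factorₗ over carried favored alleles).
  With unlinked loci and no clipping, the selection probability factorizes
  over loci, so multi-locus genotype frequencies among the *selected*
  factorize into per-locus allele frequencies — the additive-architecture
  signature the additivity test looks for. Defaults used in the bundled
  experiments (baseline 0.02, factors 3, three loci, max probability 0.54)
  keep the product uncapped.

## Sequencing model and HMM genotype calling

Per-site read depth is i.i.d. Poisson (default mean 2.5, matching the
low-coverage design point of selection-mapping studies); each read reports
the true parental allele with probability 1 − ε (default ε = 0.002). No GC,
mappability or batch structure is modeled.

Genotypes are decoded per chromosome with a two-state HMM: emissions are
binomial read-error likelihoods L(P1) = C(n, n₂)(1−ε)^{n₁}ε^{n₂} (sites
without reads are uninformative and remain in the chain so linkage imputes
through them), transitions use the Haldane fraction over the physical
distance between adjacent markers, and the state prior at each chromosome
start is fair. Decoding is forward–backward with per-step normalization; the
contract is the normalized posterior, verified against exhaustive 2^m path
enumeration to 10⁻¹⁰. Posterior decoding was chosen over Viterbi because it
yields a per-site confidence and a principled missing state: a call is made
where the larger posterior ≥ min_posterior (default 0.9). The emission
model, transition parameterization and threshold are package choices —
exposed in `HmmParams`, not fitted (no Baum–Welch); diploid/heterozygous
states are out of scope for a haploid cross.

At the defaults (2.5×, ε = 0.002, 1,200–2,400 markers) the decoder calls
>99.9% of sites with ~99.99% accuracy, and genotype error is non-increasing
in coverage (checked at 0.5×, 2.5×, 10×).

## Enrichment mapping

Only markers where the rough parent carries the non-recurrent allele
segregate in a backcross and are tested (`segregating_mask`). Markers with
identical call vectors (including the missingness pattern) across all
selected segregants carry identical information and collapse into one test,
represented by the leftmost member; on realistic dense maps this reduces
marker count by an order of magnitude or more.

Each collapsed group is tested with an **exact two-sided binomial test**
against p = ½, missing calls dropped per marker. Two-sided because either
parental allele can be the causal one in this design. For the symmetric null
the two-sided P equals 2·BinomCDF(min(k, n−k)) capped at 1; this closed form
is cross-checked in the tests against explicit tail sums and
`scipy.stats.binomtest`. Bonferroni correction uses family-wise α = 0.01
with m = the number of informative collapsed groups in that population
(correction is per population, since m varies between populations).

Loci are maximal runs of adjacent significant tested markers; the peak is
the run's largest −log₁₀ P (leftmost on ties); the **drop-2 interval** walks
outward over contiguous tested markers with −log₁₀ P ≥ peak − 2 (markers
exactly 2 below the peak are included; the first marker strictly below is
excluded). Distinct loci on one chromosome therefore require a
non-significant gap; overlapping split runs re-merge at the catalog stage.
The enriched allele is the majority allele at the peak.

## Interaction and additivity tests

**Two-locus scan.** All pairs of collapsed groups (markers within 30,000 bp
of either chromosome end excluded, both-ends closed threshold) are compared
to independence: expected 2×2 counts are n·(product of the two single-locus
allele frequencies among jointly informative segregants), χ² = Σ(O−E)²/E
with df = 1 (the 2×2 statistic with estimated margins, identical to the
Pearson independence statistic), no continuity correction. Monomorphic
groups are skipped. Benjamini–Hochberg FDR across all pairs at a stringent
10⁻⁴. Pairs on the same chromosome are flagged (`same_chrom`): linked pairs
are trivially dependent, and genotypic heterogeneity is read from the
unlinked ones.

**Additivity test.** Over L mapped loci (one peak marker per distinct locus:
overlapping calls are consolidated first and represented by their strongest
peak), observed counts over all 2^L multi-locus genotypes are compared with
expected counts n·∏ₗ fₗ(gₗ), χ² with **df = 2^L − 1**. Inclusion rules:
loci monomorphic among the selected segregants are excluded *before* the df
computation, and the test requires ≥ 2 qualifying loci (otherwise an
explicit not-applicable result). Small expected cells are kept unpooled for
fidelity to the plain-χ² convention; when any expected count is < 5 an
optional Monte-Carlo P (multinomial resampling from the expected
frequencies, seeded, default 10⁴ draws) can be attached and the condition is
flagged in the output.

In the discrimination experiments (`cryptomap.validation`), the epistatic
condition uses *two alternative AND-rules*: a single AND-rule fixes its loci
among selected segregants, which the inclusion rule would then exclude;
with two rules every rule locus stays polymorphic (segregants selected via
the other rule carry random alleles there) while joint frequencies depart
strongly from factorization — the heterogeneous, higher-order-epistatic
structure this class of experiment produces.

## Catalog consolidation

Locus calls from different GPs, backcrosses and temperature classes merge
per chromosome by single-linkage interval overlap (≥ 1 bp, 1-based inclusive
coordinates); the entry records the union interval, member calls, GP set and
an allele summary that is "both" when members disagree on the enriched
parental allele — merging deliberately ignores allele agreement, since the
same locus can be detected in either allele state in different genotypic
contexts, and the disagreement is reported rather than used to split. The
bundled call set (`data/known_loci_synthetic_intervals.tsv`) encodes the
published 21-locus catalog of the BYx3S rough-colony system — real
chromosome / GP-set / allele structure, synthetic interval coordinates —
so catalog statistics are computable without sequencing data.

## Problem sizes, determinism, limitations

The validation experiments and bundled demo run on a scaled genome — 6
chromosomes × 600 kb, 900–1,200 markers, 100–150 selected segregants per
population, 100–200 replicates per experiment — chosen to preserve the
statistical regime of the full-size design (hundreds of collapsed tests per
population, ~25-fold marker collapse, 2.5× coverage) at desk scale. Every
stochastic operation takes an explicit seed or Generator and is
bit-reproducible; the pipeline derives independent per-stage streams from
the config seed via `SeedSequence`, and rerunning a config yields
byte-identical outputs.

Not modeled: crossover interference, non-uniform recombination or marker
landscapes, coverage covariates, segmental aneuploidy, diploid
intermediates, read-level simulation or alignment, and the merging of
first- with second-generation backcross data (each generation can be run
as its own population; no combination statistic is provided). Passing tests
on the simulator therefore validate the statistical machinery under its
stated assumptions, not robustness to these real-data features.
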