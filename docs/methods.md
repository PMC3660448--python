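# Methods

## Study design being modelled

The package implements the analysis of an extreme-phenotype resequencing
design for platelet aggregation. A base cohort of two ancestry strata has
three agonist-induced aggregation phenotypes (collagen, epinephrine, ADP;
peak percent aggregation in [0, 100]) measured after aspirin treatment.
Within each stratum, each phenotype is adjusted by ordinary least squares
for age, sex, diabetes, hypertension, BMI, LDL, smoking and fibrinogen;
subjects whose residuals lie strictly above the stratum's third quartile
on **all three** phenotypes are hyper-aggregators (cases), strictly below
the first quartile on all three are hypo-aggregators (controls), and only
these extremes are "sequenced" and analyzed. Because adjustment precedes
selection, the downstream association models carry no covariates.

Quartiles are empirical quantiles with linear interpolation; a residual
exactly at a quartile is not selected. The quantile rule is a
package-level choice — extreme selection is invariant to any strictly
monotone transform of the residuals, so only tie handling at the boundary
depends on it. Hyper and hypo sets are disjoint for any tail fraction
below one half. Group sizes are taken as they come (the design does not
force equal arms).

## Single-variant tests

Each variant is analyzed within stratum on its minor-allele dosage
(0, 1, 2), re-folded to the within-stratum minor allele. Dispatch is on
the within-stratum MAF with threshold 0.05 (strict: `rare` iff
MAF < 0.05):

* **Rare:** two-sided Fisher exact test on the 2x2 allele-count table
  (minor/major x hyper/hypo). The two-sided p sums hypergeometric point
  probabilities not exceeding the observed table's probability — the
  convention that reproduces singleton p-values such as 48/102 = 0.4705
  for one minor allele among 48 case chromosomes versus none among 54
  control chromosomes. Allele counts (not genotype counts) are used; a
  variant with no minor alleles is monomorphic and gets no test.
* **Common:** logistic regression of group (hyper = 1) on dosage with an
  intercept, additive model; Wald p for the dosage coefficient. Complete
  separation or non-convergence is flagged and the p reported as missing,
  never fabricated. Wald rather than likelihood-ratio is the package
  default, matching the standard output of mainstream regression
  packages.

Results are reported as signed -log10(p) with '+' when the minor allele
is enriched in hyper-aggregators and '-' when protective, and compared to
a Bonferroni threshold alpha/m over the m tested variants (0.05/235
displays as 0.0002 under the one-significant-figure display convention).

## Burden tests

All burden tests operate on a variant set (functional class selection x
optional rare-only filter) within one stratum. Missing calls inside a set
count as dosage 0 (non-carrier) so per-subject scores remain comparable;
this is logged per run.

* **CMC collapsing.** The set is collapsed to a carrier indicator (at
  least one minor allele at at least one set variant, rare variants only)
  and tested by a 1-df Pearson chi-square without continuity correction
  on the carrier x group table, with a Fisher exact fallback whenever an
  expected cell is below 5. This is the collapsing chi-square form; the
  full multivariate Hotelling variant is unnecessary here because no
  common-variant partition enters the statistic.
* **Weighted sum (WS).** Control allele frequency with pseudocount
  q_j = (m_j + 1)/(2 n_ctrl + 2), weight w_j = sqrt(n q_j (1 - q_j)),
  per-subject score gamma_i = sum_j g_ij / w_j, statistic x = rank-sum of
  case subjects over all subjects (midranks for ties). The p-value is
  permutational: (k + 1)/(B + 1) over B random label permutations at
  fixed group sizes, k the number of permuted rank-sums at least as large
  as observed (one-sided, burden excess in cases). Weights and q are
  re-estimated from the permuted control group in every permutation, as
  in the original weighted-sum construction. B defaults to 2,000; the
  smallest attainable p is 1/(B + 1). A standardized z against the
  permutation distribution is reported alongside.
* **C-alpha.** With p0 the case fraction of subjects, each variant i
  contributes (y_i - n_i p0)^2 - n_i p0 (1 - p0), where n_i is the total
  minor-allele count and y_i the count in cases; T is the sum and c the
  exact binomial variance of T under the null. The analytic one-sided p
  comes from z = T/sqrt(c) (upper tail; dispersion excess is the
  alternative). A permutation p under the same scheme as WS is always
  computed and is the reported p when c degenerates. Each variant is its
  own category; singletons are not pooled.

The suite grid mirrors the study layout: functional classes
{missense & synonymous, missense, synonymous} x {CMC rare-only, WS
rare-only, WS all}, with an optional C-alpha column; empty cells are
reported as "no test" rather than a p-value.

## LD and tag selection

Two-locus haplotype frequencies are estimated from unphased genotypes by
the standard EM over the double-heterozygote ambiguity (convergence when
the largest frequency change is below 1e-8, capped at 1,000 iterations;
pairwise complete-case over missing calls). D = pAB - pA pB,
D' = |D|/Dmax, r^2 = D^2/(pA pa pB pb); monomorphic loci are flagged
undefined. Tags are selected by a greedy set cover at strict r^2 > 0.7:
repeatedly take the variant covering the most uncovered variants, ties
broken toward higher MAF then smaller position. Greedy cover is the
package's documented stand-in for Tagger-style heuristics; on 8-variant
instances it matches the exhaustive minimum cover in well over 80% of
random instances (verified in the test suite) but optimality is not
guaranteed in general.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any real genotype data:

* **Panel.** 235 variants over a ~32 kb single-gene region: 16 missense,
  14 synonymous, 6 5'UTR, 10 3'UTR, 48 intergenic, 141 intronic, with
  exonic positions clustered into 12 exon-like groups and 61 variants
  flagged novel. One common intronic variant (MAF 0.35/0.30 by stratum)
  is the designated index variant; eight synonymous variants (six common
  in a narrow 0.13–0.25 MAF band, two rare) form the designated burden
  set.
* **Allele-frequency spectra.** Non-coding variants are split into
  stratum-private and shared rare classes (98 rare only in the first
  stratum, 29 only in the second, 18 shared, remainder common). These
  counts were fixed once so that the realized number of polymorphic rare
  variants (MAF < 5%) in a selected cohort is about 108 in one stratum
  versus about 45 in the other.
* **LD.** Haplotypes come from a Gaussian copula: within each block
  (geometric sizes, mean 10) latent normals follow an AR(1) correlation
  (rho drawn from [0.40, 0.95]) and are thresholded at the upper
  maf-tail; blocks are independent. The designated synonymous set forms
  its own block with rho = 0.98 — long-range within-gene LD — so that a
  handful of tags covers the set. Genotypes are random haplotype pairs
  from a per-stratum pool.
* **Phenotypes.** A shared latent aggregation score combines the index
  variant (scaled to explain 39% of adjusted phenotype variance in one
  stratum, 16% in the other), the synonymous burden set (10% of variance,
  second stratum only), standardized covariate effects, and Gaussian
  noise; each agonist phenotype adds independent noise sized so the
  post-adjustment inter-agonist correlation is 0.8, then is mapped to
  mean 50, sd 15 and clipped to [0, 100]. The linear-Gaussian link is the
  simplest structure supporting the quartile design; it makes no claim of
  physiological realism.
* **Cohort size.** Base cohorts of 190 + 195 subjects yield about 104
  selected extremes under the correlation above.
* **Missingness.** Calls are masked completely at random at mean rate
  0.086. Real missingness is unlikely to be MCAR; only a mean rate is
  modelled.

Everything is deterministic given the seed: identical seeds give
byte-identical pipeline outputs.

What passing tests on this generator do **not** show: robustness to
population admixture or family structure, to informative missingness, to
non-Gaussian phenotype links, or to annotation error — none of which the
generator produces.

## Numerical and reporting choices

* MAF is always folded to [0, 0.5]; frequencies, rarity and minor-allele
  orientation are computed within each analyzed stratum.
* Missing-genotype policy differs by stage on purpose: complete-case per
  variant in single-variant tests and MAF computation; zero-fill inside
  burden sets; pairwise complete-case in LD.
* Permutation p-values use the add-one rule (k + 1)/(B + 1), so p = 0 is
  unattainable; permutation comparisons use a 1e-9 absolute guard against
  floating-point ties in rank sums.
* The burden grid's per-stratum permutation streams are seeded from the
  run seed, so reruns are reproducible.
* Degenerate inputs are refused loudly: all-missing variants (undefined
  frequency), constant dosage in logistic regression, strata under 8
  subjects for quartile selection, empty burden sets after filtering.

## Problem sizes in the shipped test suite

Calibration and recovery suites run at the design's own scale: null
calibration of CMC/WS/C-alpha uses 2,000 simulated 25+27 cohorts with 15
rare variants (MAF drawn uniformly from 0.01–0.05, a spectrum that also
keeps total minor-allele counts in the range where the C-alpha normal
approximation applies) with 500 permutations for WS; the recovery suite
uses 200 replicates of a 7-missense + 8-synonymous panel with an OR-2
in-case enrichment of the synonymous set. The Fisher implementation is
checked exhaustively against a combinatorial enumeration oracle on every
2x2 table with all margins at or below 30.

## Known limitations

* The CMC form here is the collapsing chi-square, not the original
  multivariate Hotelling statistic; with rare-only sets and no
  common-variant partition the two coincide in spirit but not in general.
* The C-alpha analytic z relies on a normal approximation that degrades
  for very sparse sets, and its variance c treats variants as
  independent: under strong within-set LD the analytic p overstates
  significance. The permutation p, computed under the same scheme as WS
  and reported alongside every C-alpha result, is the trustworthy figure
  for correlated sets.
* Greedy tagging is near-optimal, not optimal.
* Multi-allelic sites are rejected rather than decomposed.
* Strata are never pooled; no cross-stratum meta-analysis is provided.
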