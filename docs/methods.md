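# Methods

This note documents the statistical model, the quality-control cascade,
the synthetic-data generator, and the numerical and design choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Collapsing model

The unit of analysis is the gene. A sample is a *carrier* for a gene if
it has dosage ≥ 1 at ≥ 1 qualifying variant of that gene (dominant
collapsing); a sample whose calls are missing at *all* of a gene's
qualifying variants is UNKNOWN for that gene and excluded from its
tables rather than counted as a non-carrier — counting it as a
non-carrier would deflate carrier frequencies in batches with elevated
missingness.

A variant qualifies when (all thresholds strict):

* minor allele frequency < 1% in **every** ancestry group (the country
  strata by default; external per-group frequencies, when supplied, are
  held to the same rule), computed from post-QC genotypes of the combined
  case+control dataset;
* consequence ∈ {stop_gained, start_lost, frameshift, splice_canonical}
  (protein-truncating; no CADD requirement), **or** missense with CADD
  scaled score > 10.

## Association statistics

Per gene, per stratum 2×2 carrier tables feed the CMH chi-square (1 df)
with hypergeometric variances and **no continuity correction** — the
uncorrected statistic reproduces the community-biobank worked example
(chi-square 6.19, P 0.013) from its printed counts, which a Yates-style
correction would not. The Mantel–Haenszel common OR carries a
Robins–Breslow–Greenland 95% CI; single-table (display) odds ratios use
Woolf CIs with the Haldane–Anscombe 0.5-per-cell correction whenever a
cell is zero. The correction is applied per displayed table only; the
CMH statistic is always computed on raw counts. All P values are
two-sided; exome-wide significance is fixed at P < 2.5×10⁻⁶ (Bonferroni
for ≈20,000 genes), not an FDR.

The covariate-adjusted model is a maximum-likelihood logistic regression
of case status on the carrier indicator plus the top 5 ancestry PCs and
the exome-wide variant count. Separation (non-convergence, |log OR| > 15
or SE > 50) triggers a Firth (Jeffreys-prior) penalized re-fit, recorded
on the result. The Firth solver is a straightforward Newton iteration on
the modified score with step-halving.

Secondary analyses rebuild the stratum tables under restrictions:
sex-stratified runs restrict cases *and* controls to that sex; the
acute-subtype run restricts only the case column (controls have no
subtype). A report-only projection of carriers onto PC1/PC2 with
Mann-Whitney location tests screens for ancestry confounding.

## Quality control

Variant-level cascade, in fixed, logged order:

1. calls with depth < 10 set to missing (per supporting call, not per
   site — sites are not dropped for one thin call);
2. heterozygous calls with alternate-read fraction outside the open
   interval (0.20, 0.80) set to missing (boundaries mask); the behavior
   is call-level masking, with the call-rate filter re-evaluated after;
3. variant call rate must exceed 0.95;
4. Hardy-Weinberg exact test per country stratum on **all** samples
   (cases included, matching the stated stratification by country), fail
   at P < 10⁻⁴ in any stratum;
5. case-vs-control differential missingness by two-sided Fisher exact
   test, fail at P < 10⁻³ (the only phenotype-aware variant filter —
   verified by a phenotype-permutation test);
6. multi-allelic sibling rule: decomposed alleles share a parent site id
   (`chrom:pos:ref`); if any sibling fails, the whole site fails.

The HWE test is the exact conditional test: P is the total probability
of all heterozygote counts (same diploid count, same minor-allele count)
no more probable than the one observed, computed in log space with a
1e-12 tie buffer; it matches an integer-arithmetic enumeration to
< 10⁻¹⁴ over every configuration with ≤ 30 diploids.

Sample-level cascade: coverage (fraction of target bases at ≥ 20×
must be ≥ 0.80), call rate ≥ 0.95, robust outliers within stratum for
heterozygote counts and singleton counts (both tails fail for
singletons: unusually low suggests cross-contamination, unusually high
suggests degraded DNA), PCA outliers on the top 5 PCs, and duplicate/
first-degree-relative removal. Outlier cutoffs are median ± 4·MAD
(normal-consistent MAD); the source material gives only qualitative
wording here, so the 4-MAD convention is this package's choice, and
strata under 10 samples skip outlier steps with a warning. Relatedness
uses the KING-robust kinship estimator on LD-pruned common variants
with the standard cutoffs (> 0.354 duplicate, > 0.0884 first-degree);
one member of each flagged pair is kept, preferring cases, then higher
call rate. GATK-style VQSLOD filtering is out of scope (it requires the
caller's model); a numeric pass-through threshold exists for real data.

Ancestry PCA standardizes dosages by mean 2p̂ and scale √(2p̂(1−p̂)),
mean-imputes missing calls, and takes the top-5 SVD; signs are fixed by
making each component's largest-magnitude loading positive. LD pruning
is a greedy left-to-right scan on pairwise-complete r², threshold 0.1,
implemented with exact mask-matrix products so missingness never biases
the correlation.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not sequence-level reality. Defaults follow the study design: four
country strata totalling 4,667 cases and 5,473 controls (the per-country
split is not public; an even split is used), 62% of cases female, 31%
of cases with the acute subtype. Rare-variant allele frequencies are
Beta(0.2, 200) truncated at 5% (rare-skewed; the true site-frequency
spectrum of the cohorts is not published, so this is an explicit
stand-in exposed in the config); consequences are drawn from a fixed
distribution and CADD scores from per-consequence normal laws. The
number of genes defaults to 200 — a desk-scale choice; every rate and
effect-size default is independent of it.

Risk genes are spiked exactly: per stratum, controls carry with
probability q and cases with probability OR·q/(1−q+OR·q) (the exact odds
transform, not the rare-disease approximation); each carrier is assigned
one qualifying variant of the gene's risk block (AF-weighted), and all
decoy variants inside a risk gene are forced non-qualifying (synonymous,
low-CADD missense, or "other") so the realized qualifying-carrier
frequency equals q by construction. Non-risk genes draw genotypes under
Hardy-Weinberg independently of phenotype.

Sequencing artifacts are applied afterwards: Poisson(60) depth per call,
binomial read-sampling noise for allelic balance (hets at p = 0.5,
homozygotes with a 1% miscall rate), base missingness 0.2% with optional
per-stratum or per-phenotype offsets (the differential-missingness
fixture). A 2,000-site common-variant block with per-stratum AF shifts
provides recoverable ancestry gradients; LD is induced by duplicating a
fraction of common columns with copy noise; ~2% of rare-variant pairs
within a gene are merged into one multi-allelic VCF site to exercise
decomposition. All randomness flows from one integer seed through a
single generator stream; identical seed + config gives byte-identical
files.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: haplotype/LD structure beyond
duplicated columns, mutation-rate or selection models, genotype-calling
error modes beyond symmetric read noise, relatedness beyond exact
duplicates, and phenotype misclassification.

## Power

`PowerScenario` names its burden parameterization explicitly, because
the two conventions differ by nearly a factor of two in carrier pool:
`carrier` (q is the control carrier frequency) and `allele` (q is a
cumulative allele frequency; implied carrier frequency 1−(1−q)² under
HWE). Published power figures for comparable designs are frequently
silent on this convention; the acceptance script tabulates both regimes
side by side, and the tabulation (not an assertion) is the deliverable.

`analytic_power` defaults to exact enumeration: the joint binomial
distribution of pooled case/control carrier counts is enumerated over
its 10⁻¹³-mass support and the CMH rejection region summed — fully
deterministic and, by construction, in Monte-Carlo agreement with
`simulated_power` (which draws per-stratum binomial carrier counts and
applies the stratified CMH). The classical normal approximation
(pooled-variance critical value, unpooled alternative variance) is
retained as `method="normal"`; it overstates power for rare carriers at
extreme alphas by up to ~0.02 absolute, which is why it is not the
default for acceptance-grade comparisons.

## Numerical choices and degenerate inputs

* Half-missing genotypes (`./1`) are treated as missing.
* When AD is absent in a VCF, the allelic-balance filter is skipped for
  those calls (the generator always emits AD).
* Monomorphic sites return HWE P = 1; a variant with zero called
  genotypes fails call rate rather than HWE.
* Fisher differential-missingness with an all-called or all-missing
  column returns P = 1 by convention.
* Genes with all-degenerate tables are reported with NaN statistics and
  a `degenerate` flag, never silently dropped; result ordering is by
  ascending P with a stable gene-name tiebreak.
* A perfect functional predictor yields concordance-difference P = 1
  (both classes fully correct ⇒ no difference in correct-classification
  proportions).
* `results` TSVs serialize floats at 17 significant digits and
  round-trip exactly.

## Problem sizes used in checks

Oracle sweeps: every HWE configuration to 30 diploids, every Fisher
table to N = 40, 1,000 random multi-stratum tables for CMH/MH-OR.
Parameter recovery: 1,000 discovery-scale replicates (carrier-level
draws; the full-genotype path is exercised separately end to end).
Type-I error: 10,000 null replicates. Power grid: 10,000–50,000
replicates per cell. The end-to-end pipeline run uses four cohorts of
500/600 and 100 genes. These sizes are the package's desk-scale choices;
all of them are set in one place in the tests and the acceptance script.

## Known limitations

* The CMH large-sample chi-square is used even for very sparse genes;
  genes with near-zero carriers rely on the Haldane-Anscombe display OR
  and are flagged rather than exact-tested.
* The analytic power path pools strata by total n; with very unbalanced
  case:control ratios across strata the stratified test can differ
  slightly from the pooled enumeration.
* Kinship assumes a homogeneous stratum when interpreting KING-robust
  values near the relatedness threshold; admixed duplicates are still
  caught, but distant relatedness in strongly drifted strata is not a
  design target.
* No recessive or allele-count (weighted) burden models, no kernel
  tests, no meta-regression or heterogeneity statistics.
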