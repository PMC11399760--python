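# Methods

This note records the statistical model, the defaults and their
rationale, the numerical choices, and what the synthetic test bed does
and does not establish about real data.

## Per-cohort model and score statistics

Each cohort is analysed with a plain linear model of the trait on an
intercept, age, sex, BMI and principal-component covariates. Consortium
practice uses linear *mixed* models to absorb relatedness; the synthetic
cohorts here are unrelated, and with zero kinship the mixed-model score
algebra reduces exactly to the fixed-effect form implemented. This is a
documented limitation: applying the package to cohorts with family
structure or cryptic relatedness would inflate test statistics.

Score statistics residualize the dosage on the covariate design
(U = g̃ᵀe/σ², V = g̃ᵀg̃/σ²). Whether the numerator dosage should be
residualized is a genuine design choice; residualization is standard
score-test practice (it makes the score test match the Wald test of the
joint regression, which the suite asserts to 10⁻⁶ relative error) and is
what the package does. Missing dosages are handled complete-case per
variant, with no mean imputation, matching hard-called genotyping-array
practice; per-gene score covariances use pairwise-complete products so
the diagonal always equals V. Monomorphic variants carry U = V = 0 and a
flag. A residual variance below 10⁻¹² aborts variant statistics loudly
rather than emitting garbage.

The inverse-normal transform is rank-based, Φ⁻¹((r − c)/(n − 2c + 1))
with the Blom offset c = 3/8 (c = 1/2 selectable); ties get average
ranks; effect sizes are reported from the raw-trait analysis and
p-values from the transformed analysis, paired by variant identity.

Diabetes-range exclusions use inclusive thresholds (FG ≥ 7 mmol/L,
2hGlu ≥ 11.1 mmol/L, HbA1c ≥ 6.5 %) plus a treated/diagnosed flag;
missing trait values never trigger exclusion by themselves, and the rule
is monotone in every trait value (property-tested).

## QC and meta-analysis

Variant QC computes the call rate and the exact conditional
Hardy-Weinberg test (full enumeration over heterozygote counts given
allele counts, two-sided by probability ordering, no mid-p correction; a
chi-square variant is selectable). Cohort entries with HWE p < 10⁻⁴ or
call rate < 0.99 (strict inequality: 0.99 passes) are dropped per
variant before fixed-effect summation. Allele orientation is aligned by
allele match against the first cohort seen; strand-ambiguous A/T and C/G
variants are never flipped by frequency, because genotyped-array cohorts
share one strand convention. The combined allele frequency is the
n-weighted mean. Summation is associative, so within-ancestry-then-
across combination equals the one-stage result (asserted to 10⁻¹²);
the pipeline runs one global pass.

Distance-based clumping is greedy and lead-anchored: ties in p are
broken by genomic position, a lead absorbs everything within 500 kb on
its chromosome, and the partition is invariant to input order (checked
against an independent oracle re-implementation). A locus is novel iff
every member is more than 500 kb from every known trait-associated
position; otherwise the nearest known label is attached.

## Gene-level tests

Masks follow the two-tier definition (strict: PTV or 5/5-damaging
missense; broad: additionally ≥1/5-damaging missense with MAF < 1 % in
*each* ancestry group, a missing frequency failing the conjunct
conservatively); genes need at least two qualifying variants. Default
weights are w = 1 for both burden and SKAT; Beta(MAF; 1, 25) weights are
available and the choice is recorded in the output. Gene tests consume
the inverse-normal-transform statistics, consistent with single-variant
p-values; no raw-scale gene-level effect is produced. Testing
meta-combined scores is algebraically identical to meta-analysing
per-cohort gene statistics under fixed effects — the suite asserts this
equivalence rather than assuming it.

### Chi-square-mixture tail probability

SKAT needs P(Σλₖχ²₁ > q). The implementation tries three routes in
order, recording which one produced each p-value:

1. **Characteristic-function inversion** (Imhof's integral form of the
   Davies approach) over a truncated range with a certified error: the
   analytic envelope of the integrand bounds the truncation error, and
   adaptive quadrature over a few oscillations per panel bounds the
   quadrature error. When the truncated range would contain too many
   oscillations for this to certify 10⁻⁶ (typical for two or three
   small eigenvalues, where the required range holds millions of
   oscillations), the route abstains.
2. **Ruben's exact series**: the mixture is expanded as a nonnegative
   series of central chi-square tails with scale β = min λ; the
   truncation error is bounded by the unused coefficient mass, so the
   result is certified (usually to 10⁻⁹ or better) wherever the series
   converges within budget.
3. **Liu moment matching** as last resort (error bound > 10⁻⁶ or value
   outside (0, 1) upstream).

Equal eigenvalues and the single-eigenvalue case short-circuit to exact
scaled chi-square tails. Monte-Carlo validation (10⁷ draws per
eigenvalue set) uses a pre-specified two-stage protocol: a set whose
deviation exceeds 3 Monte-Carlo standard deviations triggers exactly one
fresh, independent measurement of the same size whose deviation then
stands. With 20 sets, a single-stage 3σ rule false-alarms on sampling
noise alone in roughly one run in twenty; the confirmation stage drops
that to ~10⁻⁵ while a genuinely wrong analytic value still fails both
stages. The tolerance (3 MC SDs) and draw count are unchanged by the
protocol.

## Gene-set enrichment

Input genes are the smallest-p nonsynonymous (missense or PTV) variant
per ±500 kb locus among variants with p < 10⁻⁵ (strict); loci without a
nonsynonymous variant contribute nothing. Input genes absent from the
permutation panel are removed before analysis, and the matched
permutation input size N equals the *retained* count — the alternative
(matching the pre-filter count) is unstated in the original design, and
matching the retained set keeps observed and permuted statistics on
identical footing. Removed genes still appear in the heatmap export,
flagged, because strong membership of an excluded gene is independent
supporting evidence.

Permuted association studies draw standard-normal phenotypes against a
fixed genotype panel and rank genes by their best nonsynonymous-variant
p — the same per-gene reduction as the observed side, which the original
design leaves unstated for the permuted side. Moment and FDR batches are
disjoint slices of independently seeded studies. The desk-scale default
is 200 moment + 50 FDR studies (configurable up to the full-scale
2 000 + 50); at 200 studies the permutation moments are noticeably
noisier, which widens the null spread slightly but leaves the
calibration checks passing.

Enrichment p-values are one-sided (upper tail): the statistic is a sum
of membership z-scores and only excess membership is of interest;
sidedness is switchable. The empirical FDR at p₀ is the mean over
held-out studies of the count of null p ≤ p₀, divided by the observed
count of p ≤ p₀, monotonized to be non-decreasing in p and capped at 1 —
this ratio form is one concrete reading of "comparing observed p-values
to a permuted p-value distribution" and is stated here prominently
because other readings exist.

Meta-gene sets come from affinity propagation on the set-by-set Pearson
correlation of membership z-scores, preference at the median similarity,
damping 0.5 and at most 1 000 iterations. Damping 0.5 (the sklearn
default) was chosen after measuring that 0.9 over-damps message passing
on desk-scale problems and fails to merge near-duplicate set pairs with
construction correlation > 0.99 in a substantial fraction of runs;
non-convergence falls back to singleton clusters with a warning. Each
meta-gene set is represented by its smallest-p member.

## Synthetic study conditions

The generator emulates a multi-ancestry exome-chip consortium at desk
scale: five ancestry groups with a European-dominant cohort mix (3 EUR +
1 each AFR/SAS/EAS/HISP by default), 1 000 individuals per cohort, one
shared variant panel (a fixed array), ancestry-specific allele
frequencies drawn once per ancestry as logit-normal (sd 0.3)
perturbations of a common spectrum, and a rare-heavy mixture (50 % of
variants below 1 % MAF, 25 % at 1-5 %, 25 % common). Genotypes follow
Hardy-Weinberg proportions; an inbreeding-coefficient mode exists solely
to give the HWE filter true positives, and uniform missingness exists
solely to exercise the call-rate filter. Phenotypes are
baseline + covariate terms + planted additive effects + Gaussian noise
with residual sd 0.5 trait units — small enough that the natural
fraction of simulated individuals beyond the diabetes cutoffs stays
realistically low (a few percent), on top of an explicit 2 % planted
into the diabetes range and 1 % flagged as treated. Principal components
are simulated as Gaussian covariates rather than computed from
genotypes, since only the adjustment mechanics matter at this scale.
Cohort effects are homogeneous by default (the fixed-effect model is
then exactly correct); an optional between-cohort effect sd exists for
robustness experiments.

What the generator does **not** emulate: linkage disequilibrium
(variants are independent), relatedness and population admixture within
a cohort, genotyping batch effects, and informative missingness.
Passing tests therefore establish the correctness of the statistical
machinery under its stated assumptions, not robustness to those
real-data complications.

## Problem sizes used in validation

The validation harness runs at sizes chosen to make each check sharp on
a single CPU: the pooled-regression oracle uses 3 cohorts, 2 000
individuals and 500 variants (agreement is exact to rounding, so size
only needs to exercise the bookkeeping); type-I calibration uses 1 000
null replicates of a 10-rare-variant gene at n = 800; effect recovery
uses 300 replicates of a MAF-0.30 variant with β = 0.05 at n = 1 200;
enrichment calibration uses an 80-gene panel with 200 + 50 permutation
studies and 50 seeded power runs. The reference tables shipped under
`src/glycometa/data/` are plain-text transcriptions of published
exome-array glycemic-trait association results used as worked-example
inputs; the pipeline never requires them.

## Known limitations

- No mixed models: related individuals are out of scope.
- No LD-aware conditional analysis; clumping is purely distance-based.
- X-chromosome male dosages are assumed coded {0, 2} upstream; the
  package does not verify ploidy.
- Heterogeneity statistics (Cochran's Q, I²) are deliberately absent;
  the combination is fixed-effect only.
- The summary-statistic file schema is this package's declared dialect;
  public deposits vary and may need column renaming on import.
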