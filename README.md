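# glycometa

Rare- and common-variant association pipeline for glycemic traits on
exome-array data: per-cohort covariate-adjusted score statistics,
fixed-effect meta-analysis within and across ancestries, mask-based
gene-level burden and SKAT tests, distance-based locus definition with
novelty calls, and permutation gene-set enrichment with empirical FDR and
meta-gene-set clustering. A synthetic-data generator with planted ground
truth makes every stage testable end to end at desk scale.

## Who it is for

Statistical geneticists who want a transparent, fully tested
reimplementation of the summary-statistic machinery behind exome-chip
consortium analyses of fasting glucose (FG, mmol/L), ln fasting insulin
(FI, ln pmol/L), 2-hour post-challenge glucose (2hGlu, mmol/L) and
glycated hemoglobin (HbA1c, %) — either to analyse simulated designs, to
re-run gene-level tests from cohort score files, or to study the behaviour
of these statistics under controlled conditions.

## The statistics

For each cohort, individuals in the diabetes range (FG ≥ 7 mmol/L,
2hGlu ≥ 11.1 mmol/L, HbA1c ≥ 6.5 %, or treated/diagnosed) are excluded,
and an ordinary least-squares null model of the trait (raw and rank-based
inverse-normal transformed) on age, sex, BMI and principal components
yields residuals *e* and residual variance σ². Each variant's dosage
*g*, residualized on the covariates to *g̃*, gives a score statistic and
its variance

    U = g̃ᵀe / σ²,    V = g̃ᵀg̃ / σ²,

so that β̂ = U/V, SE = 1/√V and z = U/√V. U and V are summed across
cohorts passing QC (Hardy-Weinberg exact p ≥ 10⁻⁴, call rate ≥ 0.99)
under a fixed-effect model; effect sizes are reported from the raw-trait
stream and p-values from the inverse-normal stream. Coding variants with
p < 2.2×10⁻⁷ are clumped into loci (lead-anchored, ±500 kb) and flagged
novel when farther than 500 kb from any known trait-associated position.

Gene-level tests run per mask — **NSstrict** (protein-truncating variants,
or missense unanimously damaging by SIFT, PolyPhen HumDiv/HumVar, LRT and
MutationTaster) and **NSbroad** (additionally missense damaging by ≥1
predictor with MAF < 1 % in every ancestry) — on the meta-combined scores
and their covariance *C* = G̃ᵀG̃/σ²: a burden test T = wᵀU with variance
wᵀCw, and SKAT Q = Σ wⱼ²Uⱼ², whose null law is the mixture Σ λₖχ²₁ with λₖ
the eigenvalues of WCW (tail probability by characteristic-function
inversion with an exact series and moment-matching fallbacks). Gene
significance uses the Bonferroni threshold 0.05/20 000 = 2.5×10⁻⁶.

Gene-set enrichment follows the permutation design of co-expression
"reconstituted" gene sets: input genes are the best nonsynonymous variant
per locus at p < 10⁻⁵; each gene set's observed sum of membership
z-scores is standardized against permuted association studies (random
normal phenotypes on real genotypes, top-N genes matched to the observed
input count); empirical FDR comes from a held-out batch of permuted
studies, and correlated sets are grouped into meta-gene sets by affinity
propagation, each represented by its best-p member.

## Worked example

```python
from glycometa import (SimConfig, CausalGene, simulate_all_cohorts,
                       compute_cohort_scores, combine_scores, merge_raw_int,
                       significant_coding, clump, classify_novelty,
                       build_masks, run_gene_tests)
from glycometa.synthetic_data import simulate_annotations, ancestry_mafs

cfg = SimConfig(
    n_cohorts_per_ancestry={"EUR": 2, "AFR": 1},
    n_individuals=1000, n_variants=120, n_genes=12,
    causal_genes=[CausalGene(gene="GENE00", effect=0.12, trait="FG")],
    seed=7)
cohorts = simulate_all_cohorts(cfg)
annotations = simulate_annotations(
    cfg.variant_panel(), cfg.variant_gene_assignment(),
    seed=7, maf_by_ancestry=ancestry_mafs(cfg))

raw  = combine_scores([compute_cohort_scores(c, "FG", "raw") for c in cohorts])
int_ = combine_scores([compute_cohort_scores(c, "FG", "INT") for c in cohorts])
results = merge_raw_int(raw, int_)

hits = significant_coding(results, annotations)       # coding, p < 2.2e-7
for locus in classify_novelty(clump(hits, trait="FG"), known=[]):
    print(f"locus lead={locus.lead.label} p={locus.lead_p:.2e} "
          f"members={len(locus.members)} novel={locus.novel}")

for res in sorted(run_gene_tests(build_masks(annotations), int_),
                  key=lambda r: min(r.p_burden, r.p_skat))[:2]:
    print(f"{res.gene} {res.mask}: n_var={res.n_var} "
          f"p_burden={res.p_burden:.2e} p_skat={res.p_skat:.2e}")
```

prints

```
locus lead=sv000000 p=5.25e-21 members=3 novel=True
GENE00 NSstrict: n_var=3 p_burden=9.67e-05 p_skat=6.26e-04
GENE00 NSbroad: n_var=4 p_burden=1.98e-04 p_skat=6.39e-04
```

The planted FG gene (GENE00, +0.12 mmol/L per allele on each of its
variants) surfaces as one exome-wide-significant locus of three coding
variants (its common variants reach p ≈ 10⁻²¹ at n ≈ 2 800), and tops the
gene-level ranking in both masks — while honestly staying above the
2.5×10⁻⁶ gene-level threshold at this desk-scale sample size, since the
mask tests only see its rare, damaging variants.

The same flow is scriptable: `glycometa run-all --config cfg.yaml --out
run/` executes simulate → cohort-stats → meta → gene-tests → gsea for
every configured trait and writes a manifest with per-stage output
digests; each stage also exists as its own subcommand operating on the
plain-TSV artifacts.

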