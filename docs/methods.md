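# Methods

`pathprs` implements a cross-trait association pipeline between a heritable
ordinal trait — male-pattern hair loss (androgenetic alopecia, AGA),
self-reported on a 4-level pictogram scale — and a binary severity outcome,
hospitalisation with COVID-19 among SARS-CoV-2-positive individuals. The
pipeline has four analytic stages (age-corrected epidemiological regression,
cross-trait LD score regression, genome-wide polygenic risk scores, and
pathway-restricted polygenic risk scores with FDR control) plus a synthetic
cohort generator that makes every stage testable with known ground truth.
This note records the models, defaults, and design choices.

## Synthetic cohort generator

### Genotypes

Diploid dosages are produced by a threshold-Gaussian haplotype model. Per
variant *j* an allele frequency *f_j* is drawn uniformly from `maf_range`
(default 0.05–0.5). Variants are grouped into consecutive blocks of
`ld_block_size` (default 10). Within a block, each haplotype's latent
Gaussian variables share pairwise correlation `within_block_corr`
(default 0.8) through a single shared factor; a latent value above the
(1 − *f_j*) normal quantile makes that haplotype carry the coded allele, and
the dosage is the sum of two independent haplotypes. Blocks are mutually
independent, giving tunable within-block r² against a ~zero between-block
background. The model reproduces Hardy–Weinberg dosage moments
(mean 2*f*, variance 2*f*(1−*f*)) by construction; it does not attempt
realistic recombination maps, population structure, or relatedness.
Simulated variants never use strand-ambiguous (A/T, C/G) allele pairs, so
harmonisation of simulated tables is lossless; ambiguous pairs are exercised
in tests through hand-written tables.

### Annotation and gene-set libraries

Genes are tiled with fixed length (default 1 kb) and a fixed intergenic gap
(default 20 kb), split evenly across chromosomes:
`start_{k+1} = start_k + gene_length_bp + intergenic_gap_bp`, 1-based
inclusive coordinates throughout. Three libraries emulating KEGG-2019,
WikiPathways-2019 and Panther-2016 style collections are generated, each with
`n_pathways_per_library` (default 50) pathways of `genes_per_pathway`
(default 20) genes drawn without replacement per pathway; pathways overlap
freely, as real libraries do. When `planted_pathway_id` is set, the first
library's first pathway carries that name and its genes become the planted
gene set.

### Phenotypes

Two ages are simulated because the two regression stages use different ones:
age at assessment (uniform on `age_range`, default 52–83, the age span of
the emulated cohort) and age at event (assessment plus up to 8 years),
the age at hospitalisation or most recent positive test.

Male AGA liability is

L = √h² · G + β_age · (age_assess − mean) + √(1−h²) · ε,

where *G* is the standardised genome-wide genetic score over
`n_causal_variants` (default 50) causal variants with Gaussian weights,
h² = `aga_h2` (default 0.3, the scale of twin/GWAS heritability estimates for
AGA), β_age = `aga_age_slope` (default 0.03 pattern units/year, giving
roughly one pattern level across the cohort's 31-year age span), and ε is
standard normal. The 4-level pattern cuts L at three fixed thresholds placed
at the quantiles of the analytic liability distribution implied by the target
marginal frequencies (default 31/23/27/19% for patterns 1–4, matching the
self-reported distribution in the emulated cohort; the uniform age term makes
the realised marginals approximate, not exact). Females carry no pattern
(missing), as in the emulated data source.

Hospitalisation is Bernoulli under a logistic model

logit P = β₀ + β_age,c · (age_event − mean) + δ · S,

with β_age,c = `covid_age_log_or` (default 0.05/year), δ =
`shared_effect_size` (default 0) per SD of the standardised planted-pathway
genetic score *S*, and β₀ root-solved so the mean risk equals
`covid_base_rate` (default 0.09, the hospitalisation fraction of the emulated
cohort). Everyone in the cohort is SARS-CoV-2 positive; hospitalisation
implies positivity.

When a pathway is planted, a fraction `planted_causal_fraction` (default 0.2)
of the AGA causal variants is forced into variants mapped (<10 kb) to
planted-pathway genes, and *S* is the standardised score built from the AGA
weights restricted to those mapped variants. This makes the shared component
a *pleiotropic* one — the same variants, with proportional effects, drive
both traits inside the pathway — which is the structure a pathway-restricted
PRS with AGA-derived weights can detect. Shared effects are exactly zero at
every variant at distance ≥ 10 kb from all planted genes.

### Model-consistent summary statistics

For testing the LD score regression estimator directly, paired z-scores are
drawn per variant from the bivariate sampling model

Var(z_i) = 1 + N_i h²_i l_j / M, Cov(z₁, z₂) = √(N₁N₂) · r_g √(h²₁h²₂) · l_j / M,

with the sample-overlap term fixed at zero (the emulated GWAS pair excluded
overlapping cohorts; the estimator keeps a free intercept regardless). Betas
and SEs are back-filled under unit phenotypic variance (se = 1/√N).

## Epidemiological stage

The ordinal pattern is treated as numeric 1–4 and residualised on age at
assessment by OLS (one residual per man); hospitalisation is then regressed
on the residuals by maximum-likelihood logistic regression with age at event
as a covariate. Wald tests with observed-information SEs are used
throughout. An age-window option restricts the regression to a subset
(default subset analysis: 52–59, where the severe-balding prevalence ratio
peaks). The prevalence table compares severe balding — patterns 3+4 or
pattern 4 only — between hospitalised men and a general male population
across seven age groups (52–54, 55–59, then 5-year bins to 79, then 80–83);
bin (lo, hi) covers [lo, hi+1) on the continuous age axis. The bin count is
configurable since reasonable alternatives (six wider groups) exist.

## GWAS and harmonisation

Per-variant association uses OLS via the Frisch–Waugh projection (linear
trait) or a batched per-variant Newton–Raphson logistic fit (binary trait),
each adjusting for age; both match `statsmodels` fits to ~1e-6 (tested).
Monomorphic variants are emitted with missing effect and flagged;
non-converging logistic fits are flagged and skipped, never fatal.
Harmonisation aligns a summary-statistic table to a reference orientation by
id (positional fallback), negating betas for swapped alleles, complementing
strand flips, and removing palindromic (A/T, C/G) and irreconcilable
variants outright — the conservative standard, since frequency-based rescue
of palindromic variants needs allele-frequency columns the pipeline does not
require. Harmonisation is idempotent.

## LD score regression

LD scores are l_j = Σ_k r²_{jk} over variants within a physical window
(default 1 Mb) on the same chromosome, self-term included, so l_j ≥ 1; an
optional finite-sample bias adjustment r² − (1−r²)/(n−2) is available.
Heritability is the slope of the weighted regression of χ² on N·l/M with a
free intercept; genetic covariance is the slope of z₁z₂ on √(N₁N₂)·l/M; the
genetic correlation is r_g = gencov/√(h²₁h²₂). Weights default to
1/max(l_j, 1), a single-pass heteroskedasticity weighting; the full
iterative weighting of the reference implementation is out of scope and
isolated behind one function. SEs come from a leave-one-block-out jackknife
over 50 contiguous variant blocks (fewer than the reference tool's 200,
scaled to desk-size variant counts). Intercepts are always free. When either
heritability estimate is non-positive, r_g is reported as undefined with a
reason code and both h² values, never as a silent NaN.

A deliberate design decision: the end-to-end pipeline estimates r_g from
model-consistent "published-scale" summary statistics (N = 20 000 by
default, h²₁ from the simulation config, h²₂ = 0.05, r_g implied by the
planted ground truth) rather than from the desk-scale cohort GWAS. A cohort
GWAS at M ≈ 2000 and n ≤ 20 000 with a concentrated causal architecture
carries far too little information for LD score regression — heritability
estimates swing negative in most replicates — and the analysis this pipeline
reproduces likewise ran LDSC on large published GWAS, not on its own cohort.
The cohort GWAS is still computed, written, and used for PRS weighting.

## Polygenic risk scores

Scores are plain weighted allele counts ("sum-calculation mode"):
score_i = Σ_j β_j · dosage_ij over variants with GWAS p strictly below the
threshold (defaults 5×10⁻⁸ and 5×10⁻⁵), never re-fitted on the phenotype.
Greedy LD clumping (default r² ≥ 0.1 within 250 kb, the defaults of the
standard scoring tool; disableable) runs before scoring, with deterministic
(p, chromosome, position) tie-breaking. Hemizygous male X dosages default to
the 0/2 coding (`zero_two`), with a `zero_one` option; both are exposed
because the emulated analysis did not state its coding. Missing dosages
contribute zero and are counted. Association is logistic regression of
hospitalisation on the z-scored PRS plus age at event, per sex, so reported
betas are log-odds per PRS standard deviation.

## Pathway-restricted PRS

Variants map to genes when the distance from the variant position to the
gene interval is *strictly* below 10 kb (0 inside the gene); variants may map
to several genes but enter a pathway's variant set once. Per iteration — a
(sex × threshold × library) cell — each pathway's variant set (clumped
genome-wide first, then intersected; clump-within-pathway available behind a
flag) is scored and tested exactly like the genome-wide PRS, and the
iteration's p-values are Benjamini–Hochberg adjusted. BH is implemented
directly (sort, step-up minimum, cap at 1) and cross-checked against
`statsmodels.stats.multitest` in tests. The FDR family is the iteration cell
by default; a per-library pooling is available since the emulated analysis's
granularity ("per iteration") is ambiguous. Pathways with fewer than
`min_variants` (default 1) variants are excluded and logged; failed
regressions are flagged and excluded from the family size m.

## Numerical and degenerate-input choices

* Logistic fits raise an explicit separation error on non-convergence,
  perfect separation, or non-finite SEs instead of returning unusable
  estimates; per-variant GWAS fits are flagged instead, and the scan
  continues.
* Control:case ratios are reported rounded to one decimal (the "1:x"
  presentation convention) and as an undefined marker (None) when a stratum
  has no cases.
* A constant balding pattern yields all-zero residuals with a warning; a
  constant age is a rank-deficiency error.
* All coordinates are 1-based inclusive internally (VCF convention); the
  BED-like annotation export converts to 0-based half-open at the boundary
  and declares the convention in a header comment.
* Identical configuration including the seed reproduces bit-identical
  outputs; each generator operation draws from its own seed substream so the
  stages are individually reproducible.

## What the generator does and does not emulate

The generator reproduces the features the pipeline's statistics depend on:
block LD, Hardy–Weinberg dosages, an age-dependent ordinal trait with
realistic marginals, an age-dependent binary outcome at a realistic base
rate, pathway-confined pleiotropy, and sampling-model-consistent summary
statistics. It does not emulate population structure, relatedness,
imputation uncertainty, realistic recombination, X-chromosome inheritance in
the simulated cohort (X handling is exercised through hand-built fixtures),
or selection effects in cohort recruitment. Passing tests therefore
demonstrate the correctness and calibration of the *procedures* under the
stated generating models, not the robustness of the original findings to
real-data complications.

## Problem sizes used in the automated checks

Calibration and recovery checks run at deliberately desk-sized conditions:
type-I calibration at n = 5000 individuals × 2000 variants × 50 pathways ×
200 replicates; planted-pathway recovery at n = 20 000 (the generating
effect is 0.3 log-odds per pathway-score SD) × 20 replicates; LD score regression recovery at M = 2000, N = 20 000, 20
seeds; the confounding demonstration at n = 20 000 with 40 variants × 50
replicates. These sizes were chosen so the full statistical suite completes
in minutes while keeping Monte-Carlo error well inside the asserted
tolerances.
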