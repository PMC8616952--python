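# Methods

## Pipeline

The analysis takes four inputs — GWAS summary statistics, cohort
genotypes (which double as the LD reference), a gene/regulatory
annotation and a pathway gene set — plus a phenotype table, and proceeds
in six steps.

**1. Pathway regions and SNP assignment.**  Transcript intervals of the
pathway genes are unioned with any regulatory-element intervals annotated
to the same symbols and merged per chromosome (overlapping or book-ended
intervals coalesce; book-ended merging cannot change SNP membership).
All coordinates are 1-based fully closed; BED input is converted on read;
chromosome labels are normalized by stripping a leading `chr`.  Gene
symbols are matched case-insensitively after uppercasing; alias
resolution is out of scope.  Variants whose position falls inside a
merged interval (both bounds inclusive) are assigned to the pathway.

**2. LD clumping.**  Greedy: the remaining SNP with the smallest GWAS
p-value becomes an index SNP (ties broken by chromosome, position, id)
and removes every remaining SNP within 250 kb whose squared Pearson
genotype correlation with it exceeds 0.1.  Window and r² cutoff are the
conventional C+T defaults and are configurable.  Dosage correlations are
computed on mean-imputed, standardized columns of the LD reference.

**3. Threshold-grid scoring.**  The grid is {floor} ∪ {k·step} ∪ {upper},
deduplicated ascending, with defaults floor = 5×10⁻⁸, step = 0.001,
upper = 1 (1001 thresholds).  Effect alleles are harmonized to the
genotype coding: a swapped allele pair flips the dosage (d := 2 − d),
strand-ambiguous palindromic SNPs (A/T, C/G) and irreconcilable pairs are
dropped with a warning, and missing dosages are imputed as twice the
effect-allele frequency of the non-missing individuals.  The raw score
is the unaveraged Σ β·dosage.  Because the SNP subsets are nested in the
threshold, all columns are produced by one cumulative pass over the
p-ordered clumped SNPs; columns are then z-scored, with zero-SNP or
zero-variance columns left all-zero and flagged degenerate.

**4. Threshold selection.**  For each threshold the phenotype is
regressed on the score column plus covariates; the best threshold
maximises the score coefficient's |Wald statistic| (smallest threshold on
ties).  For the linear family the statistic is computed through the
partial-correlation identity t = r·√df/√(1 − r²) on covariate-residualized
vectors, which is algebraically the OLS Wald t and lets the permutation
test run as two matrix products.  The empirical p permutes phenotype rows
(covariates held fixed), recomputes the max over thresholds of |t| for
each permutation, and reports `(1 + #{max_perm >= max_obs}) / (B + 1)` —
family-wise over the grid.  Binary phenotypes use per-threshold logistic
fits (exact but slower); the permutation scheme is the same.
Freedman–Lane residual permutation is noted as an alternative but not
implemented.

**5. PC-PGS.**  Degenerate columns are removed, the remaining columns are
centered and scaled (correlation-matrix PCA — the columns are already
z-scored, so this coincides with covariance PCA), and the leading right
singular vectors give the loadings.  Each loading vector is flipped so
its sum is positive, making PC1 correlate positively with the mean score;
otherwise the sign would be arbitrary and would flip downstream
regression coefficients.  Per-individual component scores are z-scored
before modeling.  Two components are retained by default.

**6. Phenotypes, models, FDR.**  Four binary social variables are coded
from raw questionnaire answers (loneliness yes→1/no→0; ability to
confide "almost daily"…"about once a month"→0, "once every few
months"…"never"→1; social contact: lives alone and never visited→1, not
alone or weekly visits→0, uncovered combinations missing; social
activity: ≥1 weekly group activity→0, none→1).  Combinations the printed
rules do not cover are treated as missing rather than guessed.
Continuous metabolic variables are clustered by complete linkage on the
distance 1 − |Pearson r| (pairwise-complete observations; the absolute
value keeps negatively coupled pairs together), cut at three clusters,
and each cluster is summarised by the first PC of its z-scored members
(variables have incommensurable units, so scaling is required; the PC
sign follows the cluster's first member).  Association models are OLS
for continuous outcomes and maximum-likelihood logit for binary ones:
`outcome ~ predictor + sex + age (+ 10 genetic PCs) + partners +
predictor×partners`, where the interaction partners are the outcome's
co-cluster members, or for binary outcomes the binaries found dependent
by Pearson's χ² (no continuity correction).  The genetic PCs always
enter the logistic models and, by default, the linear models too (a flag
restores the narrower covariate set).  Wald tests give all p-values;
Benjamini–Hochberg FDR is applied once across the whole family of fitted
models; interaction terms are reported with raw p-values.  Models are
fitted on complete cases.

## Specificity test

For the fitted model of interest, 100 random gene sets of equal gene
count are drawn from the annotated gene universe; for each, the entire
pipeline is rebuilt (regions, assignment, clumping, scoring, threshold
selection or PCA, model refit) and the predictor coefficient collected.
The observed beta's percentile rank is `100·#{null ≤ observed}/n`, and
the effect is flagged as pathway-specific when the rank is ≥95 (upper
tail) or ≤5 (lower tail) — a signed, direction-specific comparison.
Random sets yielding no scorable SNPs are resampled, preserving the
count.  Equal-SNP-count matching (within 10%) is available as an option,
since SNP count drives score variance.

A design point discovered during development: if the pathway's *genes*
are removed from the sampling pool, then at a small gene universe the
null sets share genes with each other but never with the pathway.  The
shared genes give the null effects a common random shift per data set
(intra-class correlation ≈ overlap fraction), so the empirical null is
too narrow around a displaced centre and the flag rate under a global
null roughly doubles.  The pipeline therefore draws null sets from the
full annotated universe and forbids only the identical set, which makes
a truly random "pathway" exactly exchangeable with its nulls.  With a
genome-scale universe (thousands of genes, sets of ~10⁻²·universe) the
two schemes coincide; `sample_gene_sets` still offers gene-level
exclusion (`exclude_genes=True`).

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
not any particular cohort.

*Genotypes.*  60 genes, 10 per chromosome, 1 Mb apart (beyond the
clumping window, so blocks are independent), 20 SNPs per gene spaced
100 bp.  Per gene, haplotype alleles are drawn by thresholding
exchangeably correlated latent Gaussians (correlation `ld_block_rho`,
default 0.95) at the gene's MAF (uniform in [0.05, 0.5]), and two
haplotypes are summed — Hardy–Weinberg dosages with strong within-gene
LD (realized genotype correlation ≈ 0.85, appropriate for SNPs within a
couple of kilobases).  2000 individuals by default.

*Summary statistics.*  The causal architecture is sparse: one causal SNP
per pathway gene (evenly spaced positions, deterministic), each with
true per-allele effect 0.02; all other SNPs are null.  Marginal betas
are true effect plus Gaussian noise with the standard marginal-regression
standard error `se = 1/√(2·N·maf·(1−maf))` at N = 300,000 (a
consortium-scale meta-analysis); p-values are two-sided normal.  This
architecture is what C+T scoring assumes: the causal SNP is usually its
block's most significant SNP, so clumping retains it, and the score
tracks the true burden closely.  A dense architecture (every pathway SNP
causal with equal effect) was tried first and rejected: after r² > 0.1
clumping a single index SNP cannot tag a 20-SNP equal-effect block
(corr(PGS, true score) plateaus near 0.85–0.9), which would make the
generator's own end-to-end recovery contract unattainable at the
designed effect size.

*Phenotypes.*  A latent adiposity factor carries the standardized
pathway effect (default 0.1) on the true causal burden plus sex and age
contributions and noise.  Nine continuous variables load on three
factors — body fat (loadings 0.92 on the latent factor), diet (0.75) and
grip-strength/waist-hip ratio (0.63), the last two coupled 0.15 to the
latent factor — chosen so the three correlation clusters separate
cleanly and the cluster PCs explain ≈88%, ≈71% and ≈70% of their
clusters' variance, the regime reported for these phenotype families.
The four social variables are drawn with realistic prevalences
(0.18/0.14/0.05/0.30) and a logistic dependence (slope 0.3) on the
latent factor, and are emitted as raw questionnaire strings so the
coding rules are exercised end to end; 1% of entries are missing; ten
synthetic genetic PCs are standard normals.  All draws come from one
`numpy.random.default_rng(seed)` stream consumed in the documented order
genotypes → summary statistics → phenotypes.

*What the generator does not emulate:* realistic demography or
recombination-based LD decay, genotyping error, relatedness,
cross-chromosome stratification (the genetic PCs are pure noise), or
UKB-scale missingness patterns in dietary variables.  Passing tests
therefore show the pipeline's statistical machinery is correct and
calibrated under its stated assumptions, not that any real-data result
would replicate.

## Numerical choices and degenerate inputs

- Thresholds, clumping ties and best-threshold ties all break
  deterministically (ascending threshold, (p, chrom, bp, id), smallest
  threshold).
- Score columns with no SNPs or zero variance are flagged and excluded
  from selection and PCA rather than silently imputed.
- The residual-projection |t| is clipped away from |r| = 1 by 1e-15 to
  avoid overflow; it matches statsmodels' OLS Wald t to 1e-8 in tests.
- A constant phenotype, an empty gene set, a gene set absent from the
  annotation, perfect separation in a logistic fit, and rank-deficient
  designs raise informative errors.
- Permutation p-values use the add-one convention, so they live in
  [1/(B+1), 1] and are valid at any B.

## Problem sizes used in the test suite

Simulation-based tests run at deliberately modest sizes chosen as the
package's own defaults for a laptop-scale check: cohorts of 500 for the
calibration studies (permutation uniformity, specificity type-I error),
the full 2000-individual default for parameter recovery, threshold grids
with steps of 0.01–0.02 instead of 0.001 where the grid density is not
itself under test, and 100 random gene sets per specificity run.  The
full suite completes in a few minutes.

## Known limitations

- Clumping uses the cohort itself as LD reference; an external reference
  panel would differ slightly.
- The logistic selection path refits a model per threshold and is slow
  for large grids with many permutations.
- No shrinkage weighting (LDpred/lassosum-style), no cross-ancestry
  portability, no sex-stratified models, no mediation analysis.
- "Equal size" for random gene sets defaults to equal gene count; the
  optional SNP-count matching is approximate (within 10%).
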