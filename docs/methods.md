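# Methods

This note documents the statistical procedures implemented in `stratmeth`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Study design

The pipeline targets a two-stage design. A *discovery* cohort is ranked by
a polygenic risk score (PRS); the top and bottom two quintiles (40% each,
`round(0.4·n)` half-up, so 41/41 of n = 103 and 27/27 of n = 67) form
High/Low comparator groups, discarding the middle fifth of "average" SNP
burden. A per-CpG linear model contrasts the strata on methylation
M-values. The per-CpG effect sizes then weight a poly-methylomic profile
score (PMPS) evaluated in *independent* samples, where general linear
models test whether the methylation signature tracks the polygenic score
and clinical grouping.

## Polygenic scores

Clumping + thresholding (C+T) with the conventions of the standard tooling:

* Variant QC: intersection of genotype panel and summary statistics with
  allele matching (swapped A1/A2 flips the dosage to `2 − d`; unresolvable
  pairs are dropped and logged, never raised); strand-ambiguous (A/T, C/G)
  SNPs removed; MAF ≥ 0.05 and INFO ≥ 0.8, boundaries inclusive.
* Clumping: greedy by ascending p; an index SNP removes neighbours within
  250 kb at r² > 0.1 (dosage correlation in the analysed panel itself — no
  external LD reference). Ties in p break by genomic position, lower first.
  The 250 kb / 0.1 defaults are the named tool's defaults; the source study
  names the tool but not the parameters.
* Score: average-per-allele, `(1/2m) Σ b·d`, matching the tool's default;
  `average=False` gives the raw sum. Missing dosages impute as 2·MAF.
* Threshold choice: Nagelkerke pseudo-R²
  `[1 − exp((2/n)(LL₀ − LL₁))]/[1 − exp((2/n)LL₀)]` of a case/control
  logistic fit per p_T on the grid {5e-8, 1e-5, 1e-4, 0.001, 0.005, 0.017,
  0.05, 0.105, 0.229, 0.5, 1}; the grid includes the optima conventionally
  reported for bipolar (0.105), depression (0.017) and cross-disorder
  (0.229) scores. Samples with missing phenotype (high-risk participants
  coded unknown) are excluded from the fit; separated fits are skipped,
  not fatal.
* Relatedness: method-of-moments IBD from IBS counts (the classical
  plink-style estimator with z's clipped to the simplex); pairs with
  pi_hat ≥ 0.1 flag the member with more missingness (tie: later sample
  id). Ancestry: classical MDS of the IBS distance matrix
  `1 − shares/(2m)`, components scaled by √eigenvalue, giving C1/C2
  covariates. Outliers: per-sample mean IBS distance to its 4 nearest
  neighbours, Z-scored across samples, excluded at Z > 4. The
  mean-of-4-neighbours statistic is one of several readings of the
  published rule; it is the one implemented and documented here.

## CpG selection and methylation QC

The analysis probe set is the intersection of four filters, reported in a
fixed order (variability → blood-variable list → blood–brain correlation →
probe-SNP): 10th–90th percentile β range strictly > 0.05; membership of a
blood-variable reference list; |mean blood–brain r| ≥ 0.3 (sign-agnostic,
optional — disabling it reproduces the larger "supplementary EWAS"
configuration with a correspondingly tighter Bonferroni threshold); and no
annotated SNP within 50 bp of the probe. A probe with no blood–brain r is
treated as failing that filter and counted separately. Being a pure
intersection the retained set is invariant to filter order.

β values are clipped to [1e-6, 1 − 1e-6] before the logit; M = log₂(β/(1−β))
with the exact inverse used throughout.

Cell composition is estimated by constrained projection onto purified
reference profiles (Houseman-style): per sample, min ‖x − Rw‖² s.t. w ≥ 0,
Σw ≤ 1, solved on the β scale with SLSQP (the 6-dimensional problem needs
no dedicated QP solver; solutions match a grid-search oracle to ~1e-6).
The β scale is a documented choice — reference profiles are β-scale.
Smoking is inferred from the AHRR sentinel CpG (cg05575921): β < 0.75
flags a probable smoker, strictly (0.75 itself is a non-smoker).

## EWAS

Per probe, OLS of M-values on the stratum indicator (Low = 0, High = 1)
with covariates sex, age, MDS C1/C2, tissue source (categorical), six cell
fractions and k surrogate variables. The coefficient sign convention makes
negative = hypomethylated in the High-PRS stratum.

* **Surrogate variables** are the leading left singular vectors of the
  residual matrix after projecting out the fixed design. The number k is
  chosen by Buja–Eyuboglu permutation: each leading eigenvalue share is
  compared with its null distribution over B = 20 within-probe permutations
  of the residuals; components are kept sequentially at permutation
  p < 0.05. This two-step variant (residual SVD + BE selection) is
  deterministic given the seed; it deliberately diverges from iteratively
  re-weighted SVA.
* **Variance moderation** (on by default, `moderate_var=False` to disable)
  shrinks residual variances toward a scaled inverse-χ² prior fitted by
  method of moments on log-variances; the moderated t gains the prior
  degrees of freedom. All calibration properties hold with it off.
* **Empirical-null correction**: t-based two-sided p and the coefficient
  sign give z = sign(b)·Φ⁻¹(1 − p/2). The z vector is modelled as
  π₀N(μ₀,σ₀²) + π₁N(μ₁,σ₁²) + π₂N(μ₂,σ₂²), fitted by Gibbs sampling (5000
  iterations, 2000 burn-in) with Dirichlet(5,1,1) weights, null mean prior
  N(0, σ₀²) with unit pseudo-count, inverse-gamma(2,1) variance priors, and
  alternative mean anchors at ±4. Identifiability requires more than the
  priors: the alternative means are sampled from normals **truncated to the
  null's tails** (beyond μ₀ ± 3σ₀), and components are relabelled each
  sweep so the null has the smallest |mean|. Without the truncation the
  mixture splits a pure wide null between components and underestimates
  inflation. Posterior means give bias = E[μ₀], inflation = E[σ₀];
  z_corr = (z − bias)/inflation (an affine, rank-preserving transform) and
  p_corr is two-sided normal. Fewer than 1000 z-scores triggers a warning.
* **Multiple testing**: Bonferroni α/m reported at full precision and 3
  significant figures (0.05/35,907 → 1.39×10⁻⁶; 0.05/214,352 → 2.33×10⁻⁷);
  Benjamini–Hochberg q-values across probes. QQ tables use the rank-0.5
  expected quantile convention; the "inflection point" reporting threshold
  defaults to p < 0.002 and is a user-set constant, not an algorithm.

## PMPS and validation models

PMPS_i = Σ b_j β_ij over discovery CpGs with p_j < p_T (strict) present in
the target set after its QC; absent probes are dropped and counted.
Defaults: β-scale target values, raw (uncorrected) discovery coefficients,
sum not mean — all four switches are exposed (`scale`, `weight_field`,
`aggregate`, and the p field) because the published description does not
pin them down; the defaults are the PRS-analogous reading, and corrected
coefficients are not used because the empirical null rescales z, not
coefficients.

Validation GLMs use type-III sums of squares with effects-coded factors
(matching the univariate-GLM convention of mainstream statistical
packages): per term F, p, and partial η² = SS_term/(SS_term + SS_resid),
with Shapiro–Wilk normality of the outcome reported per group. The
interaction model adds PRS and PRS × group. The exploratory
family-environment model regresses PMPS on FACES, PRS, group, PRS × group
and FACES × group plus age and sex, reporting Wald χ² = (b/SE)² per
single-df term and the omnibus F p.

## Gene mapping and enrichment

Regulatory domains are built basal-plus-extension: basal = TSS − 5 kb to
TSS + 1 kb (strand-aware), extended outward up to 5 kb but never into a
neighbouring gene's basal domain; coordinates are 1-based inclusive.
The 5 kb distal limit follows the printed configuration; the more common
1 Mb default is available via the `distal` argument. Probes map physically
(within the gene body), through domains, or both (union, deduplicated;
multi-mapping retained). Enrichment is the one-sided hypergeometric upper
tail per gene set intersected with the background, BH-corrected across
sets; significance is read at q ≤ 0.05. The MHC region is *not* excluded,
and no correction is made for gene length or probe density — both are
known biases of this enrichment style and are documented limitations.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with explicit seeds everywhere and bit-identical outputs per seed+config:

* **Genotypes**: biallelic dosages from a latent-Gaussian AR(1) copula
  thresholded at MAF quantiles — realistic *local* LD for clumping
  behaviour without coalescent machinery. Defaults: 1,200 SNPs in 60
  blocks (block ρ = 0.7, MAF ~ U(0.05, 0.5)) — a desk-scale panel that
  keeps clumping/IBD non-trivial. Sib-pairs (off by default) share 50% of
  haplotypes in expectation to exercise pi_hat filtering.
* **Summary statistics**: β̂ = β + N(0, SE²) with SE = 1/√(2·MAF(1−MAF)·N),
  N = 50,000 by default; 40 causal SNPs with effects ~ N(0, 0.12²); INFO
  ~ U(0.8, 1) with a configurable low-INFO fraction.
* **Methylation**: logit-scale baseline from a bimodal mixture (hypo- and
  hyper-methylated modes), plus cell-type deviations mixed by per-sample
  Dirichlet fractions (six leukocyte types at concentrations mirroring
  typical blood proportions), batch effects (SD 0.15 logit units), probe
  noise (SD 0.5), and a shift of `coupling_effect` logit units per SD of
  the standardized polygenic score at 50 coupled probes. Coupling on the
  logit scale keeps β in (0,1) with unbounded effects. The AHRR smoking
  probe is generated below 0.75 for smokers (2% of samples by default,
  matching the handful observed in a blood cohort of this size) and ≥ 0.85
  for non-smokers.
* **Phenotypes**: liability = √h²·PRS + √(1−h²)·ε with h² = 0.25 (the
  common-variant share of bipolar liability); cases above the 90th normal
  percentile; a configurable fraction of non-cases with the highest
  residual liability labelled high-risk, giving CON < HR < CASE mean PRS
  by construction; age, sex, tissue source, batch, family id and a FACES
  family-environment total ~ N(100, 15) round out the sample sheet.

What the generator does **not** emulate: genome-wide LD maps and realistic
allele-frequency spectra, array-level artefacts (the pipeline consumes
normalized β), cross-reactive probes, trans-ethnic structure, and any
non-linear PRS-methylation relationship. Passing tests therefore show the
*procedures* are correct and calibrated under the assumed generating
model, not that real cohorts will show these effect sizes.

## Problem sizes and numerical choices

Evaluation experiments run at deliberate desk scale: null calibration uses
cohorts of 103 (82 analysed after stratification) with 5,000 generated
probes and 20 seeded replicates; PMPS transfer uses 200 + 200 samples with
2,000 probes, coupling 0.4, 20 replicates; deconvolution error uses 300
probes, 50 mixtures, noise SD 0.02. The Gibbs sampler always runs its full
5000/2000 schedule in these experiments. β clipping at 1e-6; design
matrices are rejected (with the offending columns named) rather than
silently reduced when collinear; clump ties break by position; quantile
stratification ties break by stable sample-id order; the BH step-up is
monotone-enforced. Probes with missing M-values fit complete-case with a
minimum of 20 samples.

## Limitations

* The empirical-null mixture is weakly identified by construction; the
  tail-truncation constraint resolves it but means very diffuse true
  signal (alternatives inside ±3σ₀ of the null) is absorbed into the null,
  slightly inflating σ₀ — conservative for discovery.
* IBD moments use observed allele frequencies; with few SNPs pi_hat is
  noisy and the 0.1 threshold will flag some unrelated pairs.
* Type-III tests assume the effects-coded parameterization; unbalanced
  designs with empty cells are rejected by the rank check rather than
  reparameterized.
* The PMPS scale/weight conventions follow a documented reading of an
  underspecified description; all switches are exposed.
* Differentially methylated *regions*, mixed models for related samples,
  IDAT-level normalization and imputation are out of scope.
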