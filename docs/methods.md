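# Methods

`omicsmr` implements an integrated association and causal-inference workflow
for protein biomarkers measured alongside genome-wide SNP dosages and CpG
methylation in a cohort with family structure, together with a synthetic
cohort generator that provides ground truth for every stage. This note
documents the statistical models, the generator, the numerical choices, and
the known limitations.

## The polygenic mixed model

Every kinship-aware analysis is built on the Gaussian variance-component
model

    y = X b + g + e,      g ~ N(0, σg² · 2K),      e ~ N(0, σe² · I)

where `K` is the kinship matrix on the coefficient-of-kinship scale
(diagonal 0.5, full sibs and parent–offspring 0.25), so `2K` is the genomic
relationship matrix and the narrow-sense heritability is
`h² = σg²/(σg²+σe²)`. The model is fit by **maximum likelihood** (not REML).
After one eigendecomposition of `2K`, the likelihood profiles analytically
over the fixed effects and the total variance, leaving a one-dimensional
optimization over `h² ∈ [0, 1)` that is solved with bounded Brent iteration
(tolerance 1e-8); the `h² = 0` endpoint (ordinary least squares) is always
evaluated, so the reported likelihood never falls below the OLS likelihood.
Kinship eigenvalues below 1e-8 are floored ("bending") before any
inversion. When `2K` is a multiple of the identity the likelihood is flat in
`h²`; the fit collapses to OLS and is flagged `h2_degenerate`.

Kinship is estimated from common variants (MAF > 0.05) with the
allele-frequency-weighted estimator
`K_ij = ½ · mean_snp (x_i − 2p)(x_j − 2p) / (2p(1−p))`. Because allele
frequencies are estimated in-sample, realized relationships carry a small
downward offset relative to pedigree expectations (the familiar sum-to-zero
constraint of centered estimators); tests account for this.

### Association engines

* **GWAS** uses the score test on the residuals of the null polygenic fit:
  `β̂ = xᵀV⁻¹r / xᵀV⁻¹x` with `V` the fitted phenotypic covariance, and
  `β̂²·xᵀV⁻¹x` referred to a 1-df chi-squared. Dosages are residualized
  against the fixed-effect design in the `V⁻¹` inner product, so
  conditioning SNPs or an array indicator are ordinary design columns.
* **EWAS** uses a 1-df likelihood-ratio test between polygenic fits with and
  without the CpG term. The alternative likelihood is profiled over `h²` on
  a grid (step 0.04 in the genome-wide batch path) with per-probe parabolic
  refinement and one exact re-evaluation; the refinement keeps the LRT
  within well below test precision of per-probe Brent optimization.
  Effects are reported per full 0→1 change in methylation.

The two engines are deliberately asymmetric (score test for SNPs, LRT for
CpGs); they agree with plain-regression oracles when kinship is the
identity, and both hold their 5% type-I error under a family-structured
null (checked over ≥2000 null tests in the test suite). Genome-wide batch
scans run in single precision (the P-value error this introduces is orders
of magnitude below any decision threshold); single fits and small-n paths
are double precision.

* **cis-meQTL mapping** regresses covariate-adjusted methylation on dosage
  with *no* kinship adjustment, by design: a strong cis effect makes the
  methylation level quasi-monogenic, and a polygenic model would absorb the
  very signal being mapped. SNPs within ±1 Mb (inclusive) of the CpG with
  MAF > 0.01 are tested; significance is declared at 5e-8.
* **Genomic inflation** λ is the slope of the zero-intercept regression of
  observed on expected 1-df chi-squared quantiles, using all points.
* **Regions** are single-linkage clusters of significant tests within 2 Mb
  on a chromosome (boundary inclusive); the lead is the smallest P, ties
  broken by position then id. Within-region independence of CpGs uses
  greedy forward selection at P < 0.05 by the same LRT engine.

### Multiple testing

Primary thresholds are Bonferroni: 0.05 divided by the number of SNPs or
CpGs actually tested (both denominators are recomputed per run and logged),
plus the stricter GWAS variant 5e-8 divided by the number of biomarkers.
Benjamini–Hochberg q-values are available for reporting.

## Explained-by-SNP classification

For a biomarker whose EWAS and GWAS leads fall within 2 Mb (inclusive) of
each other, the CpG is re-tested with the biomarker's independent GWAS
lead SNPs (primary plus conditional leads) as fixed covariates, under the
same kinship LRT. With `t` such tests run in the analysis and `m` CpGs
tested epigenome-wide, the adjusted P classifies the association as

* fully explained (P_adj > 0.05/t),
* partially explained (0.05/m < P_adj ≤ 0.05/t), or
* not explained (P_adj ≤ 0.05/m).

`t` is always the number of adjustment tests actually performed, never a
constant. Squared marginal and partial (SNP-conditioned) correlations are
reported alongside. A companion check adds smoking to the model and flags
environmental confounding when a scan-significant association loses
significance (P > 0.05) with smoking included.

## Heritability decomposition

`ĥ²` is tested against `σg² = 0` by a 1-df LRT. The chi-squared reference
ignores the boundary (the null pins a variance at zero), which makes the
test conservative; this convention is kept deliberately, and a 50:50
mixture reference is not applied. Adjusting for top SNPs or CpG levels and
re-optimizing `h²` gives the reduction LRT (df = number of non-aliased added
columns) together with `ĥ²` before and after. Single `ĥ²` estimates have
sampling SD ≈ 0.15 at n ≈ 250, so before/after orderings are only meaningful
in aggregate.

## Mendelian randomization

Exposure and outcome are covariate-adjusted and standardized to SD 1 (the
rank-inverse-normal biomarkers already are), so causal estimates are per SD
of the exposure. Instruments are cis-regulatory: for a biomarker, all
independent genome-wide-significant SNPs within ±1 Mb of its encoding gene;
for a CpG, the single most significant cis-meQTL below 5e-8. The first
stage is OLS of exposure on instruments; the fitted value is the genetic
score (GS). Instrument strength is `F = ((n−k−1)/k)·R²/(1−R²)` with a
weak-instrument warning below 10. The second stage regresses the outcome on
the GS under the polygenic model: the slope is the causal estimate and the
P-value comes from the 1-df LRT.

The **standard error** uses the textbook 2SLS residual convention: the
error variance is estimated from the structural residual
`y − β̂0 − β̂1·x` (original exposure), GLS-weighted at the fitted `h²`,
because the second-stage residual on the fitted GS systematically
overstates it. No further first-stage correction is applied; simulation
shows 95% CI coverage of ≈ 96–98% at the default design. Because
instrument selection and estimation use the same cohort, every result
carries a winner's-curse flag.

Validity guards: inference is refused when the exposure's instrument locus
lies within 2 Mb of the outcome's own signal region (no direct IV→outcome
path — the 2 Mb operationalization matches the region convention);
bi-directional analysis additionally requires the two directions'
instruments to be pairwise independent (dosage correlation P > 0.05),
otherwise the verdict is "not evaluable". The first stage accepts any
number of instruments (the three-instrument notation of the underlying
regression generalizes to arbitrary k).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
every causal edge recorded:

* **Genotypes.** Founder haplotypes copy, block by block (default 10 SNPs),
  one of 8 pool haplotypes drawn in Hardy–Weinberg proportions at target
  MAFs uniform on (0.05, 0.5); the small pool induces within-block LD.
  Families are two parents and two offspring (100 families in the n=600
  default, the rest unrelated singles); children receive one parental
  haplotype per block (free recombination between blocks), so the pedigree
  yields an analytic expected-kinship matrix. Imputation realism: per-SNP
  info scores near 1 with a 2% low-info tail, and dosage noise scaled by
  (1 − info), clipped to [0, 2].
* **Methylation.** Each CpG has a latent logit-scale value: planted parents
  (cis SNP, smoking, protein trans effects) plus cell-composition loadings
  on background CpGs plus Gaussian noise, observed as
  beta = expit(mu0 + latent) with per-CpG baseline mu0 ~ U(−1, 1). The
  logit→beta map attenuates latent correlations by roughly 15–30%; planted
  effects (below) are sized so that planted structure remains detectable at
  n = 600 under the epigenome-wide Bonferroni threshold. Scenario CpGs
  deliberately carry no cell loading so that covariate adjustment does not
  rescale the MR exposure away from its planted standardized effect. A
  0.2% fraction of detection calls fail (large detection P).
* **Biomarkers.** Protein values sum planted cis-SNP effects, smoking,
  causal CpG effects, a pedigree polygenic term (share 0.2–0.3 by
  scenario), small covariate effects, a plate intercept (SD 0.15,
  emulating residual post-normalization plate differences), and noise
  chosen so the total variance is ≈ 1. The lowest 2% per biomarker is
  censored below the detection limit (missing), with uncensored values
  retained for oracle checks.
* **Scenarios.** Each biomarker is generated under one of: SNP_CONFOUNDED
  (one cis SNP → both protein and a nearby CpG), PROTEIN_TO_CPG (cis SNP →
  protein → trans CpG on another chromosome, which also has its own
  cis-meQTL), CPG_TO_PROTEIN (cis-meQTL → CpG → protein, the protein also
  having its own cis SNP so both MR directions are evaluable),
  SMOKING_CONFOUNDED (smoking → both), or NULL. Default standardized
  effects: cis variance fractions 0.35, causal and trans slopes 0.5,
  smoking edges 0.6, smoking prevalence 0.2.

Generation follows the topological order of the causal graph (CpGs without
protein parents, then proteins, then protein-driven CpGs) with key-derived
RNG streams so the full bundle is a pure function of the configuration.

**What passing tests do and do not show.** The generator reproduces the
features the analysis relies on — family relatedness, LD clumping, bounded
beta-values, batch effects, detection limits, confounding structure — but
not probe-specific measurement error, cell-type interactions,
population stratification, non-Gaussian protein tails, or realistic
genome-wide LD decay. Recovery rates measured here bound what the method
can do when its assumptions hold; they do not certify performance on real
cohorts.

## Problem sizes used in validation

The test suite and the acceptance script size their simulations as follows
(package choices): classification recovery runs the full default cohort
(n=600, 20,000 SNPs, 5,000 CpGs, 12 biomarkers) over 20 seeds; heritability
recovery uses n=800 sib-family cohorts over 50 seeds per true value; MR
recovery and directionality use n=600 cohorts with the default effect sizes
on a reduced marker grid (2,000 SNPs, 400 CpGs over 50 seeds) — the MR
estimand and its power depend on the sample size and planted effects, not
on the count of null markers; determinism is verified on an n=240 cohort
(4,000 SNPs, 800 CpGs) since bit-level reproducibility is scale-free.

## Numerical and edge-case conventions

* Positions are 1-based; all windows (cis ±1 Mb, region 2 Mb, criterion-2
  zone 2 Mb) are inclusive at both ends.
* Constant predictors yield missing P-values with a reason code, never an
  exception mid-scan.
* Rank-inverse-normal transform: normal quantiles of (rank − 0.5)/n with
  average ranks for ties, then exact re-standardization; all-equal input
  returns zeros with a warning.
* Aliased design columns are dropped by rank-revealing pivoted QR with a
  logged warning; a design that explains the phenotype exactly is an error.
* Below-detection-limit biomarker values are missing, never imputed.
* Detection-masked methylation calls (< 2% per probe after call-rate QC)
  are mean-imputed on the adjusted-residual scale inside the pipeline so
  genome-wide scans stay vectorized; library functions keep them missing.
* Probe-level call-rate filtering runs before individual-level filtering.
* TSV outputs use fixed float formatting, making pipeline reruns
  byte-identical.

## Known limitations

* ML (not REML) variance components are slightly biased at small n; the
  boundary LRT for h² is conservative.
* The meQTL scan's lack of kinship adjustment trades a small inflation risk
  for sensitivity to quasi-monogenic cis effects.
* The 2SLS standard error omits a first-stage correction beyond the
  residual convention described above.
* λ estimated by regression over all points is sensitive to a handful of
  very strong true signals; on scans with planted effects λ can exceed 1
  without indicating miscalibration (the null-calibration tests use
  signal-free cohorts).
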