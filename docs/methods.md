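# Methods

## The problem setting

A breeding population of ~1,300 cattle genotyped at high density
(hundreds of thousands of autosomal SNPs) and phenotyped for 13 growth,
carcass and meat-quality traits is used to (a) design a low-density SNP
panel by merging four preselection strategies and (b) validate the panel
by genomic prediction against the full chip.  The package implements every
stage — QC, relationship matrices, REML variance components, GWAS,
Bayesian whole-genome regression, panel selection, prediction and
evaluation — and pairs them with a synthetic-data generator so that every
stage can be tested against known truth.

## Models

### Animal model and REML

For trait y (n×1) with fixed effects X (sex, year, entry weight, fattening
days, plus the top genomic PCs where noted):

    y = Xb + a + e,   a ~ N(0, σ²_a G),   e ~ N(0, σ²_e I)

G is the VanRaden genomic relationship matrix built from minor-allele
dosage codes M: `G = (M − P)(M − P)′ / 2Σ pᵢ(1−pᵢ)`, with P's columns
equal to 2pᵢ.  Monomorphic markers are rejected (their centering and
denominator contribution are undefined).

REML works on error contrasts: K spans the orthogonal complement of
col(X), so K′y ~ N(0, σ²_a K′GK + σ²_e I).  One eigendecomposition of
K′GK makes every likelihood evaluation O(n).  Fitting runs EM first (the
EM map for this two-component diagonal model has a provably non-decreasing
restricted likelihood — asserted in tests), then switches to
average-information Newton steps with step-halving and projection onto a
non-negativity floor (1e-8 × var(y)); convergence at |Δlogℓ| < 1e-8 or
200 iterations.  Standard errors come from the inverse AI matrix, the SE
of h² by the delta method.

Aliased fixed-effect columns (e.g. dummy levels absent from a training
subset, or a dummy block summing to the intercept when the reference
level is absent) are dropped greedily in keep-first order rather than
raising: cross-validation subsets produce such designs routinely.  The
phenotype-adjustment step (`adjust_phenotypes`), by contrast, treats a
rank-deficient design as a user error and names the collinear columns.

The bivariate animal model shares one G between two traits with
unstructured 2×2 genetic and residual covariance matrices.  It is fit by
direct maximization of the restricted likelihood on G's eigenbasis
(per-eigenvalue 2×2 blocks λΣ_G + Σ_E), with both matrices parameterized
by log-Cholesky factors — this keeps them positive definite throughout,
serving the same purpose as eigenvalue flooring.  Starting values split
the sample covariance of the standardized traits evenly between the
genetic and residual parts.  r_G = cov_G12/√(σ²_G1 σ²_G2) and
r_P = cov_P12/√(σ²_P1 σ²_P2) with cov_P = cov_G + cov_E.  Note the
restricted likelihood is unbounded when the two traits are numerically
identical (both covariance matrices singular along the same direction);
exact duplicates are a degenerate input.

### Mixed-model GWAS (MMRA)

Two stages: the polygenic null model (fixed effects + top-3 PCs of G +
GRM random effect) is fit once by REML; every SNP s is then tested by
generalized least squares with the null covariance V = σ̂²_a G + σ̂²_e I
held fixed: α̂ = s′Py / s′Ps, Var(α̂) = 1/s′Ps, 1-df Wald χ².  Exact
per-SNP REML would move p-values slightly; the fixed-covariance test is
the standard fast approximation and is what the null-calibration check
exercises.  Monomorphic SNPs report α̂ = 0, p = 1.

### Bayesian alphabet

One Gibbs kernel (numba-compiled) serves BayesA/B/Cπ on
y = Xb + Σ xᵢgᵢ + e with centered dosage columns:

* fixed effects: flat priors, Gaussian full conditionals;
* σ²_e ~ scaled-inv-χ²(ν_e = 4, s²_e), s²_e = var(y)/4 so the prior mean
  is half the phenotypic variance (a weak, scale-matched default);
* marker effects: BayesA gives every marker its own
  σ²_gi ~ scaled-inv-χ²(v_g, s²_g) (π = 0); BayesB zeroes an effect with
  probability π (default 0.999 for preselection on the full chip, 0.995
  for prediction on a preselected panel), sampling the indicator from the
  marker's likelihood with the effect integrated out given the current
  variance; BayesCπ uses one common σ²_g and samples π from its Beta full
  conditional under a uniform (0,1) prior.
* v_g = 4.234 in the preselection profile and 4.2 in the prediction
  profile, following the conventional defaults of the respective analyses.

The scale follows s²_g = E(σ²_gi)(v_g − 2)/v_g with
E(σ²_gi) = σ̂²_a / ((1 − π) Σ 2pᵢ(1−pᵢ)), σ̂²_a from REML.  For BayesCπ,
where π is unknown, the scale is anchored on an assumed 1% non-null
fraction; with a much more diffuse anchor the sampler can settle in a
many-tiny-effects mode on null data in which π mixes poorly and does not
concentrate.  When no REML estimate is supplied the additive variance
defaults to half the phenotypic variance.

Chains: the "full" profile is 50,000 cycles with 10,000 burn-in; the
"test" profile 5,000/1,000.  Posterior summaries are post-burn-in means
without thinning (thinning configurable).  The variance of the sampled
genetic values is traced and its effective sample size (initial positive
sequence estimator) reported as a mixing diagnostic.

DGVs use raw 0/1/2 codes: DGV_j = Σᵢ Z_ij ĝᵢ with posterior-mean effects.

### GBLUP

Variance components by REML on the training subset; breeding values are
solved two ways on every fit — the covariance path
u = σ²_a G_{·t} V_t⁻¹(y − Xβ̂) and the joint mixed-model equations over
all genotyped individuals (G⁻¹ with a 1e-8 ridge when singular) — and the
paths must agree to 1e-6, an algebraic identity of the model that doubles
as a permanent internal cross-check.  SNP-BLUP equivalence (ridge on
centered markers with matched effect variance) is verified in tests.

## Panel preselection

* Top fraction: k = ceil(fraction × n) markers (671,204 × 0.001 → 672),
  ties broken by (chromosome, position, id).
* Sliding window: non-overlapping 500 kb tiles from position 1 — the
  "two SNPs per Mb" arithmetic implies tiling rather than a sub-width
  step; per tile the highest-MAF marker with call rate > 0.98 (ties to the
  lowest position), plus the first and last mapped marker of each
  chromosome unconditionally.
* Gene strategy: BED intervals are 0-based half-open, marker positions
  1-based; a marker at p lies in [s, e) iff s < p ≤ e.  Per gene with ≥1
  marker, the highest-MAF marker; genes without markers are counted.
* Merge: set union ordered by genome position, provenance flags
  OR-combined.  V_i uses the squared effect (the variance identity);
  a printed-form variant linear in |g| is available behind
  `squared=False`.

## QC

Filters keep records strictly above threshold: individual call rate
(> 0.90) first, then — on the retained individuals — SNP call rate
(> 0.90), MAF (> 0.01) and the 1-df Hardy–Weinberg χ² (p > 1e-6, no
continuity correction; monomorphic sites p = 1 by convention).  The order
matters because the marker statistics depend on who is kept; it is fixed
and reported.  Residual missing calls are filled with the per-SNP modal
genotype (ties to the lower code) — a deterministic stand-in for
reference-panel imputation, assessed by the masking harness (hide known
calls, impute, score the fraction recovered).  LD is the squared Pearson
correlation of genotype codes (composite LD; chip data are unphased).

## Synthetic data

Founder-mosaic model: per chromosome, founder haplotypes (default 30) get
allele frequencies U(0.05, 0.5) and internal LD from a Gaussian-copula
AR(1) latent process with correlation length 60 kb; individual haplotypes
copy founders with switch probability 1 − exp(−c·gap), c = 1e-8/bp
(≈1 cM/Mb).  This reproduces, at reduced genome size, the target decay
shape — r² ≈ 0.6 between adjacent markers falling below 0.2 within a few
tens of kb and flattening to a small background set by the founder count.
Defaults mirror the study population: 1,331 individuals, 13 traits with
heritabilities 0.11–0.56, uniform genetic correlation 0.75, sex ratio
83:17, birth years 2008–2015 with ~10% born 2014+ (enabling the forward
year-split), entry-weight and fattening-days covariates.  The reduced
default genome (5 × 10 Mb at 100 SNP/Mb) keeps routine runs fast; all
sizes are configurable.

Phenotypes: one QTL set shared by all traits, effects multivariate normal
(or Laplace via a shared scale mixture) with the target cross-trait
correlation; residuals are rescaled so the realized sample h² matches the
target exactly; fixed effects are added in phenotypic-SD units.  The
default architecture is fully polygenic (every marker causal): that is
the regime in which the GRM animal model is well-specified and parameter
recovery is a meaningful check.  Oligogenic architectures (explicit
`n_qtl`) deliberately violate it — REML h² attenuates there, which is the
realistic behaviour, and the panel-value benchmark exploits exactly that
setting.

What the generator does **not** emulate: genotyping error, pedigree
structure and selection over generations, sex chromosomes, allele-
frequency spectra shaped by ascertainment, or the phasing/imputation
machinery of reference panels.  Passing benchmarks therefore demonstrate
the correctness and calibration of the estimators under the stated
generative model, not field performance on any particular real
population.

## Benchmark problem sizes

The built-in checks run at reduced scale chosen to keep a full run in
minutes on one core: h² recovery at n = 1000, ~5,000 markers, 20 seeds;
genetic-correlation recovery at n = 1000 (3 seeds); BayesCπ sparsity
recovery at n = 500, m = 2000 with 1% causal; GWAS null calibration on
~independent markers (m = 5000, several permutations — under strong
founder LD the effective number of tests is small and a single
permutation's rejection rate is too noisy to bound); GBLUP bias and the
preselected-vs-random panel comparison at n = 1000 over 10 seeds.

## Known limitations

* The imputation stand-in is per-SNP modal fill; no haplotype-clustering
  imputation is attempted, and low-density panels are evaluated on panel
  genotypes directly rather than after imputation to full density.
* Multivariate REML beyond two traits, pedigree relationship matrices and
  single-step methods are out of scope.
* The GWAS test is score-type with fixed null covariance; per-SNP REML
  refitting is not implemented.
* BayesCπ mixing depends on the scale anchor (above); extremely diffuse
  settings on null data are slow to traverse.
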