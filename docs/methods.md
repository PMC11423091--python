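# Methods

## The two association tests

Both tests ask the same scientific question: does the genetically regulated
activity of a ChIP-seq peak (an androgen-receptor binding site or an
H3K27ac enhancer mark — a "cistrome" feature) associate with a trait?  Both
operate on individual-level data in two phases: a *training* phase that
learns per-SNP weights linking the cis-genotypes of a peak to its measured
activity in a reference cohort, and a *testing* phase that carries those
weights to an independent genotype–phenotype cohort.

**Fixed-effect test (CWAS).**  Imputed activity is the linear combination
ĉ = G_std·w of standardized test-cohort genotypes with the trained weights,
and the trait is regressed on ĉ; the peak statistic is the single-df slope
t (continuous traits) or the Wald z from logistic regression (dichotomous).
A summary-statistic variant combines SNP-trait Z scores,
z_peak = wᵀz / √(wᵀΣw), for workflows without individual data; Σ is the
SNP LD matrix, estimated from the training panel when not supplied, and a
near-singular quadratic form is regularized by Σ ← (Σ + 0.1·I)/1.1.

**Random-effect test (RECWAS).**  The per-SNP effects β_k on the trait are
treated as random, β_k ~ N(0, w_k²τ), and H₀: τ = 0 is tested with the
variance-component score statistic

    Q = (Y − Ŷ)ᵀ K (Y − Ŷ),    K = G·diag{w_1², …, w_p²}·Gᵀ,

with Ŷ fitted under the covariate-only null (least squares, or logistic
IRLS for 0/1 traits).  Under H₀, Q is distributed as Σ_k λ_k χ²₁ where the
λ_k are the eigenvalues of P^{1/2} K P^{1/2} and P is the null
variance/projection operator (σ̂²(I−H) for continuous traits;
V − VZ(ZᵀVZ)⁻¹ZᵀV with V = diag(μ̂(1−μ̂)) for dichotomous ones).
Eigenvalues below 1e−10 of the maximum are dropped.  Unlike the classical
sequence kernel association test, the kernel weights are *effect sizes
estimated in the training phase*, not minor-allele-frequency densities;
MAF-density weighting is therefore not applied by default.  Only common
variants (MAF ≥ 0.05, configurable) enter the kernel, and covariates
default to none.

Six kernels are provided (linear, weighted linear, weighted quadratic,
2wayIX, IBS, weighted IBS).  Every kernel admits an exact finite feature
map A with K = AAᵀ when dosages are integer, so the eigenvalues come from
an m×m problem (m = number of features) rather than n×n; this is what makes
simulating tens of thousands of peaks practical.  The weight exponent in
the kernel diagonal is configurable (`weight_power` 2 or 4): the natural
reading of the model is diag{w_k²}, and the power-4 alternative — squaring
already-squared weights — is exposed because the method's two published
descriptions of the weight matrix are not mutually consistent; we treat the
diag{w_k²} form as intended and default to it.

## Mixture-of-chi-square p-values

P(Σλ_kχ²₁ ≥ Q) is computed by Davies' exact method — numerical inversion
of the characteristic function on a discrete grid whose spacing comes from
Chernoff-bound cutoffs of the distribution's support and whose truncation
point comes from an analytic tail bound, with Gaussian-convolution
smoothing when the integrand decays too slowly.  Defaults: accuracy 1e−9,
term limit 10⁶.  Two special cases bypass the inversion with exact
formulas: a single eigenvalue is a scaled χ²₁, and exactly two eigenvalues
reduce, by conditioning on one chi-square, to a smooth one-dimensional
integral evaluated by adaptive quadrature to near machine precision (the
oscillatory inversion converges slowest precisely there).  If the inversion
fails or returns a value at its accuracy floor, the Liu–Tang–Zhang
moment-matching approximation is used and the result is tagged
`pvalue_method="liu"`.  P-values are clamped to (1e−300, 1].  The
large-scale simulation harness requests accuracy 1e−7: at 20,000 peaks the
numerical error is then still two orders of magnitude below the Monte Carlo
noise of any rejection-rate estimate, at a fraction of the cost.

## Weight training

* **LASSO** — activity regressed on standardized genotypes under an L1
  penalty.  The exact solution path is computed by least-angle regression
  (coefficients are piecewise linear in the penalty), and K-fold (default
  5, seeded) cross-validated MSE is evaluated on a grid of 100 log-spaced
  penalties from λ_max (the smallest penalty giving the all-zero model)
  down to 0.001·λ_max.  The selected penalty follows the one-standard-error
  convention: the largest λ whose CV error is within one SE of the minimum.
  Because λ_max is on the grid, a response carrying no signal resolves to
  the all-zero "null model" (flagged, not an error); under pure noise this
  happens in ≈ all replicates, while two causal SNPs of 50 at high
  heritability are both recovered in ≥ 95% of replicates.
* **Marginal effects** — per-SNP simple OLS on the standardized scale
  (slope = cov(G_std, C)/1), two-sided t-test with n−2 df.  Constant SNPs
  are flagged with weight 0.
* **TOP1** — the minimum-p marginal SNP carries its slope; ties break to
  the smaller genomic position.
* **Model selection** — candidates are scored by the p-value of the
  regression of observed activity on out-of-fold predictions, mirroring
  the cross-validation p-value reported by predicted-expression pipelines.

All weights live on the standardized-genotype scale; prediction and kernel
construction standardize identically (population variance, constant columns
map to zero).  Missing genotypes are mean-imputed at test time only; allele
frequencies are always computed from observed calls.

## Synthetic data

The generator emulates the benchmark design: biallelic SNPs with allele
frequency uniform on [0.05, 0.5] (two Bernoulli haplotypes per sample);
optional first-order LD via a copying process on the latent haplotype
uniforms (preserves marginal frequencies; default off); peak activity
C = C_G + C_E with the genetic component drawn under one of five
architectures — additive (Σβ_kG_k, β ~ N(0,1), n_causal ∈ {2,3,5,10}),
single-variant, and three two-SNP interaction models on *carrier status*
(dosage ≥ 1): epistatic (AND), heterogeneous (OR), compensatory (XOR).
The environmental term is N(0, Var̂(C_G)(1−h²)/h²), so Var(C_G)/Var(C)
converges to the target heritability; h² = 1 yields a noiseless cistrome.
Phenotypes follow either the causality model (the trait's genetic component
is the *noisy* cistrome: genotype → cistrome → trait) or the pleiotropy
model (the trait's genetic component is recomputed from the same causal
SNPs and effects; its noise is independent of the cistrome's).  The
description of the generating procedure mentions mapping the genetic
component onto [0, 1] before rescaling; since the subsequent variance-ratio
noising makes any affine rescaling immaterial to every test in the package,
min–max normalization is implemented as an optional flag and off by
default.  Pleiotropy shares both the causal set and β with the cistrome,
making the two disease models maximally contrasting.

What the generator does **not** emulate: realistic allele-frequency
spectra, fine-scale LD blocks, genome-scale SNP counts, population
structure, or haplotype-resolved (allelic-imbalance) signals.  Passing
benchmarks here therefore demonstrates the statistical machinery under the
stated generative model, not performance on real cohort data.

## The benchmark experiments

One simulated peak = one replicate: draw window allele frequencies; draw an
independent 400-sample reference cohort and 1,200-sample test cohort from
that population; simulate reference activity and train weights; simulate
the test trait; run both tests.  Weights are never trained on the tested
cohort.  Per-method weight sources follow the method's design: the
fixed-effect test imputes activity from the sparse cross-validated LASSO
fit (TOP1 fallback when LASSO returns the null model), while the
random-effect kernel aggregates the marginal-effect weights of all window
SNPs.  This division is what produces the characteristic power ordering:
under additive signals the sparse direction is nearly optimal and the
single-df test wins; under interaction signals or weak training the sparse
direction is misestimated and the multi-df weighted score test is more
robust.  Method failures (degenerate predictor, empty model) count as
non-rejections and are tallied.

*Type-I error*: 20,000 peaks, windows of n_snps = n_causal cycling over
{2, 3, 5, 10} (reference activity additive, h² = 0.25), test phenotypes
N(0,1) independent of genotype; rejection fraction at p < 0.05.  An
"empirical cutoff" mode (threshold at the 5% quantile of realized null
statistics) exists as a protocol sanity check — it returns 5% by
construction.

*Power*: 1,000 peaks per cell, 30 common SNPs per window with n_causal of
them causal, rejection at the study-wide threshold 0.05/5580.  Heritability
grids follow the benchmark design: causality h² ∈ {0.05, …, 0.25} for both
cistrome and phenotype; pleiotropy couples both heritabilities on
{0.01, …, 0.08}.  Representative acceptance cells: additive causality at
(h²_c, h²_p) = (0.25, 0.15); the four non-additive architectures at
(0.25, 0.25); pleiotropy additive at 0.02/0.04 and epistatic at 0.04/0.08
with a gap-widening check.  Desk-scale sizes (400/1,200 samples, 1,000
peaks per cell) are the package's default profile; all sizes are config
fields, and cell seeds derive from one master seed by counter so any cell
is reproducible in isolation.

## Peak annotation

Validation layers for significant peaks use BED-convention (0-based,
half-open) interval arithmetic: GWAS risk SNPs flanked by ±1 Mb,
susceptibility genes flanked by ±100 kb (any-base overlap in both cases,
overlapping same-label regions kept distinct), boundary-gap distances to
the nearest gene (0 on overlap, +inf when a chromosome carries no
features), and enhancer-domain-score windows counted by *peak-center
containment* in ±100 kb gene windows with EDS percentile ranks.  The two
overlap conventions (any-base vs center containment) follow the respective
definitions of the evidence layers; duplicate transcripts are deduplicated
by (label, chromosome, start, end).

## Numerical choices and limitations

* Genotypes are coded as minor-allele counts, recomputed per dataset; an
  exact frequency tie breaks to the lexicographically smaller allele.
* Standardization uses population (ddof 0) variance everywhere, so training
  and testing scales agree exactly.
* The continuous-trait null dispersion is RSS/(n−q); with the 1,200-sample
  test cohorts the distinction from the MLE is negligible.
* Dichotomous traits use the plain score test; no small-sample moment
  adjustment is applied, so case/control cohorts should not be very small
  or very unbalanced.
* The IBS feature map requires integer dosages; mean-imputed fractional
  dosages fall back to direct O(n²p) kernel construction.
* Exact LARS paths can fail on degenerate (duplicate-column) inputs; the
  trainer falls back to coordinate descent on the same penalty grid.
* Under this generator the single-variant architecture slightly favors the
  fixed-effect test at every heritability cell (TOP1/LASSO identify the one
  causal SNP essentially exactly, making the single-df test near-oracle,
  while the marginal-weight kernel dilutes the signal across the window's
  null SNPs); adding first-order LD widens rather than closes that gap.  A
  random-effect advantage for single-variant signals, where observed on
  real genotypes, evidently depends on features of real LD and weight
  estimation that this emulation does not capture, and the corresponding
  benchmark expectation fails here.  The interaction architectures and the
  pleiotropy regime reproduce the expected ordering.
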