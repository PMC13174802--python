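# Methods

This note documents the statistical model behind `stratsem`, the
conventions the implementation commits to where the literature leaves a
choice open, and what the synthetic-data generator does and does not
emulate.

## Generative model and simulator

The simulator works at the z-score level. For SNP j with LD score ℓ_j,
the vector of association z-statistics across k traits is drawn from

Σ_j = sqrt(N N') ∘ cov_g · ℓ_j / M + I,

where cov_g[a,b] = Rg[a,b] · sqrt(h²_obs,a · h²_obs,b) is the
observed-scale genetic covariance, N the per-trait effective (binary) or
total (continuous) sample size, M the SNP count, and I the intercept
matrix: unit diagonal, off-diagonal N_shared·ρ_pheno / sqrt(N_a N_b) from
participant overlap. SNPs are independent given their LD scores. This is
exactly the estimand of cross-trait LD-score regression, so parameter
recovery by the downstream engine is a sharp end-to-end check. Per-SNP
covariances are factorized by eigendecomposition with small negative
eigenvalues clipped at zero, which handles exactly-singular
configurations (e.g. two traits with r_g = 1 and full overlap, whose
z-scores are then identical by construction).

LD scores are i.i.d. shifted gamma, `floor + Gamma(shape, scale)`, floored
at 1 — positive and right-skewed like real LD scores. Defaults: mean 40,
shape 2, floor 1. A mean equal to the floor gives the degenerate
all-ones distribution used in tests. SNPs are laid out on up to 22
synthetic chromosomes with contiguous 1-based positions.

Binary traits are parameterized by liability-scale h², population
prevalence K and case/control counts. Under the summed
effective-sample-size convention the regression's observed scale relates
to liability by the conversion factor evaluated at sample prevalence
P = 0.5 (see below); the simulator therefore draws at
h²_obs = h²_liab / c(K, 0.5), making the round trip through the engine's
liability conversion exact rather than approximate.

### The four-stratum preset

`asd_strata_config()` emulates a sex- and age-at-diagnosis-stratified
autism battery: male (15,025/19,763 cases/controls, K = 0.016), female
(4,845/19,315, K = 0.004), early-diagnosed (N_eff = 33,608, K = 0.0075)
and late-diagnosed (N_eff = 21,775, K = 0.0025), each with liability h²
= 0.12, and stratum correlations r_g(male, female) = 0.81,
r_g(early, late) = 0.42, r_g(late, male) = 0.99, r_g(late, female) =
0.91. Those four values are jointly infeasible as a correlation matrix
(given r(late, male) = 0.99 and r(late, female) = 0.91, any PSD
completion needs r(male, female) ≥ 0.84), so the preset projects to the
nearest unit-diagonal PSD matrix by eigenvalue clipping and records the
largest entry change (≈0.013) in the truth record; recovery checks
compare against the projected, recorded values. The early–male (0.50)
and early–female (0.45) entries and the overlap magnitudes (shared-N ×
phenotypic correlation of 500–4,000 between sex- and age-stratified
GWAS drawn from the same cohort) are package defaults chosen inside the
feasible region; prevalences split a ~1% population prevalence by the
known male bias and diagnosis timing. The modest K values make the
liability conversion factors realistic for an ASD-like trait.

### What the simulator does not emulate

No genotypes, no real LD structure (scores are i.i.d., SNPs conditionally
independent), no annotation-stratified architecture, no per-SNP sample
size variation, no population stratification (univariate intercepts are
exactly 1 in expectation). Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the LDSC model, not
robustness to model violations in real data. Note also that at desk
scale (M ≈ 2000 with realistic N) the per-SNP signal N·h²·ℓ/M is much
larger than in a real GWAS; this inflates mean χ² but leaves the
estimand and the recovery logic unchanged.

## Quality control

`munge` reproduces the standard harmonization stage: restrict to an
allowed-SNP registry, align effect alleles to the registry orientation
(z flips sign when the pair is reversed), retain only MAF > 0.01 and
INFO > 0.9 (strict inequalities; records lacking an optional column pass
that filter), drop strand-ambiguous A/T and C/G pairs, and exclude the
MHC (default chr6:26,000,000–34,000,000, 1-based inclusive — the exact
boundaries are a package convention and overridable). Each dropped
record is attributed to exactly one rule, in the fixed precedence
not-in-registry → region → MAF → INFO → ambiguous → allele-mismatch, so
the QC report always conserves the input count.

## LD-score regression

Each (co)heritability is a two-step weighted least squares of the
per-SNP response (χ² or z-product) on x = N·ℓ/M, so the slope is already
on the heritability scale. Weights are the product of the over-counting
correction 1/max(ℓ, 1) and the inverse squared expected response
1/(2(a + h·x)²). Step one evaluates them at intercept 1 and unit slope;
step two re-evaluates at the step-one fit, clamping the slope to
[0, M·max(ℓ)/mean(N)] and flooring the expected response at 0.01 for
weighting only (numerical guards; the point estimate is never clamped).
The cross-trait intercept is left free and absorbs participant overlap.
The weighting scheme is a variance-reduction convention, not part of the
estimand; the regression is unbiased for any fixed weights.

The sampling covariance **V** of vech(**S**) (lower-triangle column
order, shared by every residual vector and Jacobian in the package)
comes from a delete-one-block jackknife over 200 contiguous SNP blocks
(default, matching the usual granularity): each block's deletion
re-estimates every entry with the step-two weights held fixed, and
V = ((b−1)/b) Σ (θ_i − θ̄)(θ_i − θ̄)'. V is PSD by construction and
asserted so on every run. Liability conversion — multiply by
c = K²(1−K)² / (P(1−P)·φ(Φ⁻¹(1−K))²) per binary trait (sqrt(c) per trait
for covariances), with P fixed at 0.5 under the effective-N convention —
is a constant factor and is applied inside each jackknife replicate.
Standardization to the correlation metric is applied within each
replicate and the jackknife formula re-applied, so the nonlinearity of
the ratio propagates into V_R; unit-diagonal rows of V_R are exactly
zero. Monte-Carlo checks confirm the jackknife SE of the standardized
estimate matches its empirical sampling SD within 25%.

## Structural models

Models are fit to (R, V_R) by diagonally weighted least squares with the
unit diagonal treated as fixed (not modeled): the data vector is the
off-diagonal vech of R, the weight matrix diag(V_R) restricted to those
elements. Implied correlations follow the reticular action model with
observed variables plus unit-variance latent factors; residual variances
of endogenous observed variables are set deterministically to keep every
implied variance at 1, so they consume no degrees of freedom and
df = (#off-diagonal elements) − (#free parameters) for every
specification.

Optimization: trust-region least squares from three jittered,
seed-controlled starts, best discrepancy kept; convergence requires the
projected gradient below 1e-8 relative to the problem's gradient scale.
Parameters are bounded on the correlation metric — correlations in
[−1, 1]; loadings, factor paths and residual covariances in [−1.5, 1.5]
(room to detect Heywood cases while blocking the ridge a fixed unit
diagonal leaves open: with all indicator correlations near zero a single
loading is otherwise unidentified and can diverge); observed regression
weights in [−5, 5] to permit suppression. Sign convention: the first
loading of each factor is constrained positive by flipping the factor.
Heywood loadings (|λ| > 1.01) and negative residual variances flag the
result but do not abort it.

Uncertainty uses the sandwich covariance
(Δ'WΔ)⁻¹ Δ'W V_R W Δ (Δ'WΔ)⁻¹ with W = diag(V_R)⁻¹ and Δ = ∂σ/∂θ at the
optimum (central finite differences, step 1e-6). Model fit uses the
residual-based statistic T = e'Γ⁺e, where Γ projects V_R onto the
residual space and the pseudoinverse is truncated at rank df. For the
single-constraint comparison the free model is saturated, so the
constrained model's χ² and a difference test against the saturated model
coincide; the 1-df Wald contrast
(r₁ − r₂)²/(var₁ + var₂ − 2cov₁₂) is co-implemented and reported
side-by-side, and the two agree to within 10% on well-conditioned inputs
(exactly, in the linear 1-df case).

Genetic multiple regression uses the closed form β = Rxx⁻¹rxy with
delta-method standard errors propagating V_R through the analytic
Jacobian, and refuses to fit when |r(predictors)| ≥ 0.95 — partial
effects of near-duplicate strata are uninterpretable, mirroring the
exclusion of a late-diagnosed stratum whose correlations with the
sex-stratified GWAS approach 1.

Factor residualization fits one common factor (unit variance, free
loadings) over ≥3 indicators, regression paths from the factor to each
target, and free residual covariances among targets. The adjusted
association between two targets is the residual covariance standardized
by the residual SDs sqrt(1 − b²); its sampling covariance follows from
the sandwich parameter covariance by the delta method, enabling a 1-df
Wald test of equal adjusted associations.

## Pipeline conventions

Traits enter the battery only if their heritability z-statistic exceeds
4 (strict). Difference-test p-values are Benjamini–Hochberg corrected
across the battery; per-stratum correlation significance is corrected as
two separate families (the alternative — one pooled family — is equally
defensible; separate families keep the difference test's error rate
interpretable on its own). The transition class of a trait under factor
adjustment is a pure function of the two FDR flags:
persists (sig→sig), attenuated-to-ns (sig→ns), newly-significant
(ns→sig), stable-ns (ns→ns).

## Problem sizes

Validation simulations use M = 2000 SNPs with 200 jackknife blocks:
recovery of the four-stratum preset over 100 replicates, type-I error of
the equality test over 500 null replicates (nominal 5%, observed within
a 3-binomial-SE band), FDR control over 50 complete-null batteries of 20
external traits, and factor-adjustment behavior over 50 replicates of a
purely factor-mediated design (where ≥80% of stratum differences are
attenuated to non-significance after adjustment). These sizes give
Monte-Carlo standard errors small enough for 3-SE recovery bands while
keeping the full suite desk-scale.

## Known limitations

- i.i.d. LD scores and conditionally independent SNPs understate the
  block dependence of real genomes; the jackknife is exercised but not
  stressed by realistic autocorrelation.
- The two-step weighting is one refinement, not iterated to convergence;
  with very small M the intercept and slope are weakly separated and
  cross-trait intercept estimates are noisy (their sampling error is
  carried honestly in the jackknife).
- Correlation-metric bounds mean a genuinely explosive Heywood case is
  reported at the bound (±1.5) with a flag rather than diverging.
- The second-order bias of the correlation ratio estimator is visible at
  very high replicate counts but stays well inside the 3-MC-SE recovery
  bands at the validation sizes above.
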