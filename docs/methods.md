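# Methods

## Model

Each calf record carries three traits: gestation length (GL, integer days),
calving difficulty (CD, ordinal score 1..C, default C = 3) and stillbirth
(SB, binary score 1..2). CD and SB are modelled on a latent (liability)
scale: the observed score is the index of the threshold interval the
liability falls in, with the `(τ_{c−1}, τ_c]` convention. For
identification the first two CD thresholds are fixed at 0 and 1, the SB
threshold at 0, and the SB residual variance at 1; any CD thresholds beyond
the second (C > 3) are free and updated from their uniform full
conditionals.

The working phenotype triple is `y_i = (GL_i − g_ref, l_CD,i, l_SB,i)`.
The structural system is strictly recursive (GL → CD → SB, no feedback):

```
Λ_k y_i = μ_i + ε_i,    μ_i = X_i b + Z_i(h) h + Z_i(s) s + Z_i(mgs) mgs
```

with `Λ_k` unit lower triangular, zero above the diagonal and in the GL
row, carrying the negated rates λ_CD←GL(k), λ_SB←GL(k), λ_SB←CD(k). The
category k of a record is determined by its realized GL (boundaries 267,
273, 279 days by default, boundary days in the lower class), so the rates
— and all reduced-form covariances `Λ_k⁻¹ Σ Λ_k⁻ᵀ` — are heterogeneous
across gestation lengths. The sign convention (negated λ off-diagonals,
so that `Λ y = μ + ε`) makes `Λ⁻¹` accumulate recursion effects with
positive sign; the total GL→SB rate is λ_SB←GL + λ_CD←GL·λ_SB←CD, the
(SB, GL) entry of `Λ⁻¹`'s action.

**The GL reference day.** The recursion covariate is the *deviation* of GL
from a fixed reference `g_ref` (simulator default: the design mean, 278 d;
fitting default: the rounded sample mean, recorded in the run manifest).
With raw GL as the covariate, category-wise slopes around a shared single
intercept would imply jumps of several liability units at the category
boundaries (e.g. 0.005·267 vs 0.020·268), which no observed score
distribution could sustain; anchoring the piecewise-linear slopes at a
common reference is equivalent to adding the category-specific intercept
shifts λ_k·g_ref and is the generative reading used throughout.

**Random effects.** Herd-year vectors `h_j ~ N(0, H0)` (3×3). Each bull
carries a joint 6-vector of sire-of-record and maternal-grandsire-of-record
effects `(s, mgs) ~ N(0, G0)` (6×6, sire block first); bulls appearing both
as sire and as MGS are what identify the sire–MGS covariances. Residuals
are iid `N(0, R0)`. No pedigree relationships among bulls are modelled
(identity assumed; the per-bull update is the natural hook for a numerator
relationship matrix extension).

**Variants.** SMM: `Λ_k = I`, all three matrices unstructured (R0 corner
fixed). RMM1: recursion + diagonal R0. RMM2: additionally diagonal H0.
RMM3: additionally G0 restricted to per-trait 2×2 (sire, MGS) blocks.
Free-parameter counts (dispersion + structural): 32 / 41 / 38 / 26.

## Priors

Unstructured covariance blocks: inverted Wishart with df = dimension + 1
and scale 0.1·I (proper, weak). Diagonal variances: scaled inverse
chi-square (ν = 4, s² = 0.1). Structural coefficients: N(0, 10⁴),
effectively flat but proper. Fixed effects: N(0, 10⁶) per coefficient —
numerically flat, and it keeps the conditional proper when a design cell
is empty. The fixed-effect design uses corner constraints (intercept plus
levels 2..L of sex, age-at-first-calving and year-season; 16 coefficients
per trait), so the posterior is proper without further devices.

## Gibbs sampler

Scan per iteration: (1) CD/SB liabilities from truncated normals — in the
RMMs the CD conditional pools its own equation with the information
flowing back from the SB equation in which l_CD is a predictor, then l_SB
given l_CD; in SMM each liability's residual is conditioned on the other
two traits through unstructured R0; (2) fixed effects and, for RMMs, the
structural coefficients; (3) herd-year vectors (conditionally independent
across levels, drawn in one vectorized pass); (4) per-bull (s, mgs)
6-vectors, scanned sequentially with an incrementally maintained residual
(two bulls can share a record); (5) free thresholds (no-op at C = 3); (6)
dispersion: inverted-Wishart conditionals for unstructured blocks, scaled
inverse chi-squares for diagonals, 2×2 inverted Wisharts for RMM3's
per-trait genetic blocks, and for SMM a *fixed-corner conditional*
inverted Wishart for R0 (sampled through the Wishart partition theorem on
the precision matrix: the free blocks keep their unconditional laws while
the Schur complement, which is exactly 1/R0[SB,SB], is pinned).

**Blocking of λ with b.** The λ's multiply a covariate whose within-
category mean is far from zero relative to its spread, so λ_k and the
trait intercept sit on a narrow ridge: single-site λ updates given b have
conditional standard deviations two orders of magnitude below the marginal
posterior spread and would need tens of thousands of scans to traverse it.
The sampler therefore draws each trait equation's fixed effects and its
λ's as one joint multivariate-normal block (CD: 16 + K coefficients, SB:
16 + 2K), an exact blocking of the same posterior. Standalone single-block
updates (`sample_location_effects`, `sample_structural_coefficients`)
exist for testing and for composing custom scans, e.g. running the joint
machinery with λ pinned at zero.

Missing phenotypes are rejected at load. Chains are deterministic given
the configuration seed (per-chain seeds are spawned from it). Default
protocol: 5 chains × 10,000 iterations, burn-in 1,000, thinning 10 →
4,500 retained draws. Convergence is not auto-stopped; summaries report
split-R̂ (flagging > 1.05) and effective sample size via arviz, plus
batch-means Monte-Carlo standard errors (⌊√n⌋ batches) and shortest-
interval HPDs computed in-package.

## Derived genetic parameters

Every retained draw (not the posterior mean) is pushed through the
reduced-form transformation per category and then through Willham's
sire–MGS relations: σ²_d = 4σ²_s, σ_dm = 4σ_s,mgs − 2σ²_s,
σ²_m = 4σ²_mgs + σ²_s − 4σ_s,mgs, with the bilinear between-trait
analogues. Heritabilities use the phenotypic variance
σ²_p = σ²_s + σ²_mgs + σ_s,mgs + σ²_e on the reduced-form scale; the
herd-year variance is excluded by default (configurable), the common
convention in sire–MGS calving-trait analyses. A draw whose implied
per-trait (direct, maternal) matrix is not PSD is counted and flagged,
never discarded — this can legitimately happen draw by draw.

## Model comparison

Fitted and predicted ordinal scores are probit expected scores: category
probabilities are differences of standard-normal CDFs at the thresholds
minus the liability estimate, and the score is the probability-weighted
category index. Fitted/predicted liabilities are the model's *expected*
liabilities given the location effects — driven by the record's observed
GL through the recursion in the RMMs, plain linear predictors in SMM. The
augmented liabilities are deliberately not used as fitted values: being
truncated to the observed category they would track the data almost
perfectly and measure nothing. Metrics are per-trait MSE and Pearson
correlation; predictive ability uses a random 3-fold partition
(record-level, so herds and bulls are shared across folds), fits on two
folds, predicts the third with plug-in posterior means (unseen levels →
effect 0), and computes the metrics once on the concatenated test sets.
Between-model concordance correlates the posterior means of the
reduced-form expected phenotypes `Λ_k⁻¹ μ` of two fits.

## Synthetic data

The generator emulates the structure of national calving-ease records at
reduced scale: defaults 5,000 records, 60 sires, 120 MGS (30% of MGS ids
also appear as sires, which is what makes σ_s,mgs identifiable), 40
herd-years, uniform assignment, GL mean 278 d. Structural-coefficient
truths use published-magnitude category profiles (λ_CD←GL rising from
0.005 to 0.040 across categories, λ_SB←CD ≈ 0.33, λ_SB←GL chosen so the
overall GL→SB effect runs from −0.044 to +0.024). Variance components are
set so that on the reduced-form scale the GL phenotypic SD is ≈ 4.9 d
with direct heritability ≈ 0.37, CD and SB direct heritabilities below
0.1, unassisted-calving frequency ≈ 65% and stillbirth incidence ≈ 9%;
herd-year variances are scale guesses (only correlations are constrained
by the emulated literature). GL is rounded to integer days and never
truncated — the outer categories absorb the tails — and the category is
determined from the realized, rounded GL, as in the phenotypic recursion.
Latent liabilities and effects go to a separate truth file that the
fitting pipeline never reads.

What the generator does *not* emulate: selection and culling, missing
records, multi-parity structure, pedigree relationships, genotypes, or
non-normal liabilities. Passing tests therefore demonstrate correctness
of the algebra and the sampler under the model's own assumptions, not
robustness to their violation in field data.

## Numerical choices and test design

- Truncated normals use inverse-CDF sampling with tail guards (an interval
  so deep in a tail that both CDF values collapse returns the nearer
  bound).
- Cross-product scale matrices get the prior scale added before inversion;
  reduced-form outputs are symmetrized against round-off; the fixed R0
  corner is set exactly, not to round-off.
- Monte-Carlo checks of the reduced-form identity condition carefully on
  the GL category: because k is a function of realized GL, conditioning
  truncates GL, so the per-category check uses GL-independent effects and
  zero GL→liability rates (the (l_CD, l_SB) block is then exact per
  category) and the full 3×3 check uses category-constant rates (one Λ for
  all records, no selection distortion). These checks also use many small
  herd/sire clusters — with few large clusters the shared effects inflate
  the sampling error of empirical covariances beyond the iid 3-SE band.
- Problem sizes in the test suite and acceptance script (5,000 records ×
  3,000 iterations for recovery; 2,000 × 2,000 × 4 variants for
  concordance; 20,000 for Monte-Carlo identities) are chosen as the
  smallest at which the targeted properties are statistically decisive.

## Known limitations

- Single-site threshold updates (C > 3) mix slowly on large data; the
  default 3-category CD needs none.
- The sampler assumes complete records; no missing-phenotype imputation.
- Herd-year variance defaults in the simulator are weakly grounded (see
  above).
- DIC and Bayes factors are intentionally out of scope as comparison
  criteria; MSE/correlation and cross-validation are the supported tools.
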