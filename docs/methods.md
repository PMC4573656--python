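# Methods

## The problem

A tree-level prediction of above-ground biomass (AGB, kg) from an
allometric equation ŷ = f(x; b̂) carries *model error* from two sources:
the residual variance σ²ₑ of the original fit and the covariance matrix
cov(b̂) of the estimated coefficients. The delta-method (first-order
Taylor) variance of an out-of-sample prediction is

    V(ŷⱼ) = σ²ₑ + gⱼᵀ cov(b̂) gⱼ,        gⱼ = ∂f(xⱼ|b)/∂b |_{b=b̂}.

Many published biomass equations report only the fitting sample size n and
a coefficient of determination R², so neither σ²ₑ nor cov(b̂) is
available. `allocov` constructs *substitutes* for both from (n, R²) plus
samples of the explanatory variables (DBH, optionally HT) drawn from the
inventory of the population the equation will actually be applied to. The
substitutes are survey-calibrated rather than reconstructions of the lost
statistics: they describe the uncertainty the equation carries *in the
target population*.

## Recovery procedures

All procedures run B resampling replicates. In replicate b, n trees are
drawn without replacement from the inventory pool, predictions are formed
on the fitted scale (the log scale for log–log equations), and a replicate
residual variance comes from the R² identity

    σ̃²ₑ,b = V(f(x_b|b̂)) · (1/R² − 1),

with V the n−1 denominator sample variance. At R²=1 the substitute is
zero; it grows without bound as R²→0. The identity treats the published
R² as exact and assumes a homogeneous error structure. Plain or adjusted
R² are both accepted; which one was supplied is recorded, never converted.

**Basic.** cov_b = σ̃²ₑ,b (FᵀF)⁻¹ with F the n×q matrix of per-tree
gradients; the substitute is the average over B of σ̃² and cov_b. For a
linear model this is algebraically the textbook least-squares covariance
on each replicate (a machine-precision test pins this down).

**Weighted.** When the original fit was weighted least squares, the same
weighting must be replicated: cov_b = σ̃²ₑ,b (FᵀWF)⁻¹ with W diagonal.
The default rule is wⱼ ∝ 1/DBHⱼ² (the common variance model for biomass
residuals); explicit inclusion weights (inverse selection probabilities,
for PPS-selected fitting data) can be supplied instead. Weights are
normalized to sum to one within each replicate — the normalization is part
of the contract because it does not cancel out of σ̃²(FᵀWF)⁻¹.

**Refit (parametric bootstrap).** Pseudo-responses y*ⱼ = f(xⱼ|b̂) + e*ⱼ
with e*ⱼ drawn from a t distribution with n−q degrees of freedom, scaled
so its variance equals σ̃²ₑ,b; the coefficients are re-estimated by
(iterative) least squares and the per-fit covariances σ̂*²(F*ᵀF*)⁻¹ are
averaged over B. If any pseudo-response is negative — impossible for
biomass, and common for equations that predict near zero for the smallest
trees — the replicate switches to multiplicative residuals y*ⱼ = ŷⱼ e*ⱼ
with e*ⱼ ~ Gamma(ν, 1/ν) (mean 1, variance 1/ν). ν solves the
first-order product-variance identity

    V(ŷe*) = V(ŷ) + ν⁻¹(ȳ̂² + V(ŷ)),

with the target V(ŷe*) set to V(ŷ) + σ̃²ₑ,b so the multiplicative scheme
matches the total variance the additive scheme would have produced; the
exact product-variance formula has no real-valued solution in typical
biomass settings. The fallback is per replicate, not per tree, and the
number of fallback replicates is reported. The fallback is skipped when
σ̃²ₑ,b = 0 (noise-free limit), where refitting returns b̂ and a zero
matrix exactly.

**Robust.** A sandwich form per replicate,

    cov_b = (FᵀF)⁻¹ (Σᵢ ẽᵢ² gᵢgᵢᵀ) (FᵀF)⁻¹,

with simulated residuals ẽᵢ from a t distribution with ⌊0.5·n⌋ degrees of
freedom scaled so the *distribution* variance (df/(df−2) factor included)
equals σ̃²ₑ,b. The deliberately low df reflect that most published biomass
equations rest on 6–30 trees: halving a sample in that range raises the
one-sided 95th t-percentile by 3–21 %, and the heavy tails guard against a
mismatch between the unknown fitting sample and the target population.
df < 3 is refused (the t variance is undefined). With homoscedastic
residuals the sandwich collapses to the basic form in expectation, which
the suite verifies at B=5000 within 10 % element-wise.

**Off-diagonal recovery.** When coefficient standard errors are published
but covariances are not, off-diagonals are recovered as the Pearson
correlation of gradient components across inventory trees times the
geometric mean of the published variances, with correlations clipped to
[−1, 1]. A robust variant weights the correlation by 1/|ẽᵢ| with
simulated t residuals (the weighting is scale-free, so the residual
magnitude does not need calibrating).

## Numerical choices

- Normal-equation matrices are inverted through SVD; a replicate whose
  smallest singular value falls below machine-rank tolerance is redrawn
  (up to 10 times, then a hard error). A returned matrix with 2-norm
  condition number above 1e8 triggers a warning — biomass gradient pairs
  such as (DBH², √(DBH·HT)) are severely collinear (coefficient
  correlations near −0.88 in the built-in beech case) and determinants are
  tiny, so downstream inversion amplifies error.
- Returned matrices are symmetrized and, if an eigenvalue is negative,
  PSD-repaired by clipping; repairs are counted and reported.
- One root seed drives everything; per-replicate generators are spawned as
  SeedSequence children, so raising B extends the replicate sequence
  without reshuffling earlier replicates, and identical seed + config
  gives byte-identical output.
- The Monte Carlo convergence monitor is the relative standard error of
  the B-average determinant of the recovered matrix:
  100·SD(det_b)/√B/|mean det_b|. The default B=800 keeps it under 4 % in
  the German-style scenario (measured ≈2 %). "Monte Carlo error" admits
  several definitions; this one is adopted and stated.

## Propagation

Species-mean model error uses the average gradient, exactly in the
average-then-quadratic-form order:

    V(ĀGB_s) = σ̃²ₑ/n_s + ḡᵀ cov(b̂) ḡ.

The mathematically different average-of-quadratic-forms is available
behind an off-by-default flag as a diagnostic only. Per-hectare variance
is λ̂² V(ĀGB) + ĀGB² V(λ̂) with λ̂ the stem density (stems/ha), assuming
zero covariance between density and mean biomass. Species totals add
variances under independence; the call refuses species declared to share
one equation, because shared coefficients correlate their model errors and
a plain sum would be wrong. For log–log equations all variances live on
the log scale; by the delta method the log-scale SE is the relative SE of
AGB on the natural scale, which is how log-scale budgets convert to
percent errors (the conversion choice is documented here because the
source tables do not state theirs). Mg/kg conversion is centralized
(1 Mg = 1000 kg).

## Comparing covariance matrices

Box's M test (chi-square approximation with the standard small-sample
correction; df = p(p+1)(k−1)/2) compares a recovered matrix to a reference
matrix, with group sizes defaulting to the fitting n for both. Its type-I
error at n=50 bivariate groups is calibrated (5 % nominal, measured within
[3 %, 7 %] over 2000 null simulations). An F-ratio test compares residual
variances two-sidedly. Degenerate comparisons of numerically zero matrices
(the noise-free limit) are reported as equality with p=1 rather than an
undefined determinant.

## Synthetic populations and what they do (not) show

Published inventory summaries give only per-species moments: mean (SD) of
DBH and HT, e.g. German beech 35 (15) cm and 25 (7) m with mean reference
AGB 1111 kg/tree, and seven Mexican species with DBH-HT moments and stem
densities. The generator moment-matches a lognormal (default) or gamma
DBH marginal in closed form and couples DBH and HT through a Gaussian
copula on the log scale with correlation 0.7 — a typical diameter-height
association; the source states no distributional forms, so these are this
package's choices, with gamma kept as a sensitivity check (AGB means are
robust to the family). Reference AGB is the equation prediction times a
uniform [0.9, 1.1] error, mirroring how the German reference biomass was
constructed. Under these defaults the generator reproduces the printed
mean AGB per tree within a few percent for beech (≈1115 vs 1111 kg) and
for the four Mexican log-log species (≈53/194/48/49 vs 54/198/50/51 kg).
The printed pine summary (mean AGB 1100 kg) is not consistent with the
printed pine equations at the printed moments (they give roughly 500 kg);
beech is therefore the calibration scenario and the pine row is carried as
data only.

The validation harness closes the loop: fit an equation to a random
sample of the population (keeping the textbook covariance and R² as
ground truth), exclude the fitting trees, recover substitutes from the
remainder, compare with Box's M, and propagate each matrix to a relative
error of mean AGB. Because fitting and recovery samples then come from
the *same* distribution, all three procedures are nearly unbiased in this
harness (basic and robust within ~5 % of the actual diagonal on average,
refit 2–10 % low through the gamma-fallback/leverage interaction). That is
the designed behaviour of the methods under distributional match; it does
*not* reproduce the orderings observed on real inventory data, where the
fitting sample came from a handful of spatially clustered plots with a
different DBH-HT distribution than the whole population. Plot-level
clustering is deliberately out of scope for the generator, so passing
tests here demonstrate correctness and internal consistency of the
procedures, not their field behaviour under distribution mismatch.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| B | 800 | replicates | determinant MC error ≤ 4 % (measured ≈2 %) |
| n | published n | trees | the fitting sample size being emulated |
| robust df | ⌊0.5·n⌋ | — | heavy tails for small-sample equations; refuse df<3 |
| refit residual df | n − q | — | residual degrees of freedom of the original fit |
| weight rule | 1/DBH² (sum-to-one) | — | standard biomass heteroscedasticity model |
| dbh_ht_corr | 0.7 | log-scale corr | typical diameter-height association |
| noise_interval | [0.9, 1.1] | multiplicative | reference-AGB construction rule |
| condition warn | 1e8 | 2-norm cond | collinear gradients amplify inversion error |

## Known limitations

- The published R² is treated as exact; a 1–2 point error in R² moves the
  recovered residual variance by 30 %+ for power-law equations. An
  empirical-Bayes treatment of R² uncertainty is out of scope.
- Recovery is refused for generalized multi-source equations (the
  registry's entries 13–15): their printed fit statistics describe the set
  of generalized models, not a least-squares fit, and recovery from them
  is known to fail.
- The substitutes are conditional on a correctly specified model; model
  bias is not addressed.
- Species sharing one equation cannot be aggregated (correlated model
  errors); change estimation between two inventories, where model errors
  largely cancel, is out of scope.
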