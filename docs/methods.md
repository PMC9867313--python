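# Methods

This note documents the statistical machinery inside `semfi`: the model,
the estimation choices, the synthetic data the tests rely on, and the known
limits of both.

## The latent nutrient model

Six observed indicators measure two first-order latent factors — total
nutrients (SOM, TN, TP) and available nutrients (AN, AP, AK) — and a single
second-order soil-fertility factor drives both. In matrix form x = Λη + δ,
η = Γξ + ζ, with no direct η→η paths (B ≡ 0): the only structural arrows
run from the second-order factor down. The implied covariance of the
indicators is Σ(θ) = ΛΦΛ′ + Θ, where Φ is the factor correlation matrix
and Θ the (diagonal, optionally augmented) error covariance.

**Identification.** All latent variances are fixed to 1 ("unit-variance
identification"), so every estimated loading and path is already on the
standardized latent scale; the fully standardized solution only divides
each loading by its indicator's implied SD. A second-order factor with just
two first-order indicators is under-identified (its two paths γ₁, γ₂ enter
Σ only through the product γ₁γ₂), so the default model constrains the two
paths equal; the package also provides the observationally equivalent
correlated-factors model, which estimates the factor correlation
φ = γ₁γ₂ directly and is used as simulation truth (φ = 0.306). With the
equal-γ constraint the default model has q = 13 free parameters (6 loadings,
1 path, 6 error variances) against 21 sample moments, df = 8.

**Estimation.** F_ML(θ) = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p is minimized by
L-BFGS-B with analytic gradients (dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)dΣ]); the model
chi-square is (n−1)·F_min. Because the free-loading/free-error-variance
family is invariant to separate rescaling of each indicator, the optimizer
works on the sample *correlation* matrix — raw soil units span four orders
of magnitude — and maps estimates back to the input scale afterwards.
Convergence requires an infinity-norm projected gradient below 1e-6; on
failure up to 5 jittered restarts are tried before a diagnostic error.
Error variances are bounded below at 1e-6: a solution at that bound is a
Heywood case, flagged with a warning rather than an exception so that
small-sample pipelines keep running. Non-positive-definite Σ during a line
search is handled by returning a large penalty value.

**Modification indices** are exact, not the usual Lagrange-multiplier
approximation: each candidate fixed parameter (error covariance or
cross-loading) is freed and the model refit from a warm start, and the
chi-square drop is reported. For models this small the refit costs
milliseconds, and the exact index is self-consistent by construction —
freeing the top candidate reproduces old χ² − MI identically.

**Squared multiple correlations** are 1 − θ_ii/σ_ii per indicator (equal
to the squared standardized loading under simple structure) and γ² per
first-order factor.

## Screening and fit battery

Cronbach's α uses the classical k/(k−1)(1 − Σσ²ᵢ/σ²_total) with n−1
variances; the pipeline computes it on z-scored indicators (α is not
scale-invariant, and mg/kg indicators would otherwise dominate g/kg ones),
jointly over all six and per nutrient group. KMO uses anti-image partial
correlations from the inverse correlation matrix; Bartlett uses the
−(n−1−(2p+5)/6)·ln|R| statistic on p(p−1)/2 df. Verdict bands: α > 0.8
high / 0.5–0.8 acceptable; KMO > 0.7 suitable / > 0.5 acceptable;
Bartlett p < 0.05.

The comparative indices use the independence baseline
χ²_B = −(n−1)ln|R| on p(p−1)/2 df (the default baseline of mainstream SEM
software). SRMR is the RMS difference between sample and implied
*correlations* over all p(p+1)/2 unique elements; the correlation diagonal
contributes zeros, and a flag excludes it for the p(p−1)/2 variant.
CR and AVE are computed over all six indicators as one composite (single
reported values; per-factor values can be had by passing per-factor loading
lists). Reference bands: CMIN/DF ∈ [1, 3], CFI/TLI/IFI > 0.90,
SRMR < 0.08, CR > 0.7, AVE > 0.5. A chi-square ratio *below* 1 is reported
"no-fit" by the letter of the [1, 3] band even though it indicates
over-fit rather than misfit; the ratio itself is always printed alongside.
TLI is undefined (reported n/a) for saturated models.

## Weighting and scoring

Weights are two-level proportional shares of the standardized paths:
β_h = γ_h/Σγ, ρ_k = λ_k/Σλ within group, W_k = β_h·ρ_k; each level sums to
1 by construction. Coefficients must be strictly positive — a negative
loading makes a proportional share meaningless and signals that the model,
not the normalization, needs attention.

Scoring is deliberately performed on **raw** measurement units, never on
z-scores: the sigmoid S = 1/(1+(x/x₀)^b) needs a positive ratio scale. The
slope is −2.5 for more-is-better indicators (all six nutrient defaults) and
+2.5 for less-is-better; the two are exact complements,
S₋b(x) + S₊b(x) = 1. The reference x₀ defaults to the indicator mean pooled
over *all* samples, not per depth layer or age group: pooling is what makes
scores, and hence SFI values, comparable across design cells, which is the
whole point of a cross-cell fertility comparison. A per-cell x₀ can be
supplied through `ScoringConfig.x0_values` when a within-stratum index is
wanted. x = 0 under b < 0 returns the limiting score 0.

## The synthetic generator

The generator emulates a designed survey — 5 age groups x 5 plots x 5
points x 4 depth layers, one core per cell (500 rows; `n_per_cell`
multiplies this) — whose indicators follow the two-factor model: two
unit-variance factors with correlation 0.306, standardized indicator
z = λf + √(1−λ²)e with the default loadings (0.89, 0.96, 0.46, 0.42, 0.78,
0.77). Standardized draws are mapped to measurement scales per cell using
per-age-group (mean, SD) targets and a depth-decline multiplier profile:
(1.00, 0.90, 0.72, 0.55) for SOM/TN/AN, flatter (1.00, 1.00, 0.90, 0.85)
for TP/AP/AK, reflecting the stronger depth stratification of organic
matter and nitrogen. Multipliers are renormalized to mean 1 per indicator
so pooled per-age-group means hit their targets exactly in expectation.
Negative normal draws are handled by resampling only the indicator's
idiosyncratic noise (clipping would put point mass at zero); AP, whose SD
rivals its mean, instead passes its standardized draw through a
mean-preserving lognormal transform and is positive by construction at the
cost of slight Pearson-correlation attenuation.

Two regimes matter:

- **Default (cell effects on)** is the study-conditions emulator. Pooling
  its 500 rows mixes cell means, so the pooled sample covariance contains
  the age/depth gradients *on top of* the factor structure — exactly the
  situation a real pooled survey presents, and one in which the two-factor
  model fits imperfectly and fitted loadings are biased away from the
  generating values (measured bias up to ~0.5 on some loadings).
- **`SyntheticSpec.homogeneous()`** switches every cell to one global
  (mean, SD) and disables the lognormal transform, giving i.i.d. draws from
  the pure factor model. This is the regime for parameter-recovery and
  covariance-convergence experiments, where the generating values are the
  estimand.

Consequently, passing tests on homogeneous data demonstrate estimator
correctness, while the default-regime tests demonstrate pipeline behaviour
under realistic survey structure — neither says the two-factor model is
*true* for any real forest soil, and the generator encodes no spatial
autocorrelation, measurement-method error, or plot-level random effects.
All 500 rows are treated as independent when fitting, inheriting the usual
pooled-survey violation of independence across depths within a core.

## Recovery precision at n = 500

At the population covariance the optimizer recovers generating parameters
to 1e-8. At the survey's sample size the ML estimator's own sampling
variation dominates: the asymptotic (inverse-Fisher-information) SEs of the
standardized loadings at the default truth are 0.023–0.053 at n = 500, so
individual loadings land within ±0.06 of truth roughly 80–98% of the time
(weakest for the 0.77–0.78 loadings), and the joint event that all six land
inside ±0.06 occurs in only about half of simulated surveys. The test suite
therefore checks what the estimator actually guarantees at this n —
unbiasedness (mean recovered loading within ±0.02 of truth across seeds)
and exact population recovery — and the stricter joint ±0.06/90% band is
exercised in the acceptance tests, where it documents this precision limit.

## Numerical conventions

- Sample SDs and covariances use the n−1 denominator throughout.
- Missing indicator cells are rejected, never imputed (the CFA needs
  complete cases and no imputation rule is defensible without auxiliaries).
- Depth layers are ordered categoricals ("0-15" … "45-60" cm), not numeric
  midpoints; all summaries iterate them in order.
- CSV round-trips are bit-exact: tables are written at full repr precision
  and parsed with correctly-rounded float conversion.
- Chi-square values are clamped at 0; CFI at [0, 1].
- Test problem sizes (200 seeds at n = 500 for recovery, 50k rows for
  covariance convergence, 40 seeds for screening gates) were chosen to keep
  Monte-Carlo error well below the asserted tolerances while the full suite
  runs in well under a minute.
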