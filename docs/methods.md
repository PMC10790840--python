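# Methods

`dyadosc` estimates patterns of physiological linkage — statistical
interdependence between two interacting people's autonomic signals —
from interbeat-interval (IBI) time series, groups dyads by the dynamics
it estimates, and relates the resulting groups to experimental
conditions and person-level covariates. This note documents the model,
the estimation choices, the synthetic-data generator, and the known
limitations.

## The coupled-oscillator model

Each partner's detrended IBI series is treated as a damped linear
oscillator coupled to the partner's oscillator. With x_A(t), x_B(t) the
detrended series (ms) on the 2-s sampling grid,

    x_A'' = eta_self_A · x_A + zeta_self_A · x_A'
          + eta_cross_A · x_B + zeta_cross_A · x_B'

and symmetrically for B. The coefficient roles:

| coefficient | units            | interpretation                                   |
|-------------|------------------|--------------------------------------------------|
| eta_self    | (sample unit)^-2 | own frequency; oscillatory iff negative, period 2π/√(−eta_self) |
| zeta_self   | (sample unit)^-1 | own damping (negative) / amplification (positive) |
| eta_cross   | (sample unit)^-2 | coupling to partner position (frequency coupling) |
| zeta_cross  | (sample unit)^-1 | coupling to partner velocity (damping coupling)   |

With 2-s windows a period in sample units converts to seconds by
multiplying by 2 (e.g. a fitted eta_self of −0.0679 implies a 24.1-unit
≈ 48-s period, about six oscillations in a 5-min task).

## Preprocessing

Beat-level IBIs are averaged into half-open 2-s windows [k·2, (k+1)·2),
giving 150 samples per person for a 300-s task. Each person's series is
then linearly detrended — OLS residuals of value on sample index, with
the intercept removed — over the whole task segment. Missing windows
are linearly interpolated when the gap is at most 3 samples (interior
gaps only); a dyad is excluded when either person still misses more
than 10% of samples. Both thresholds are configurable; they are
pipeline decisions, not estimates.

## GLLA derivative estimation

Derivatives are estimated by generalized Local Linear Approximation:
the series is time-delay embedded (dimension `embed`, lag `tau`
samples, spacing `delta` = 1 sample unit), and each embedded row is
projected onto a local quadratic in centered time via the fixed weight
matrix W = L(LᵀL)⁻¹ with basis columns (1, t, t²/2). The t²/2 scaling
makes the third output the second derivative itself; this is enforced
by an exactness test on quadratics (< 1e-9 for every grid
configuration). At embed = 3 the estimator interpolates the three
points, so the weights reduce to ordinary central differences; rows are
computed only where the full embedding exists (the series shortens by
(embed−1)·tau samples, no padding).

On a pure sinusoid of angular frequency ω the estimator is biased: the
acceleration-to-position ratio is the lagged-cosine sum
Σⱼ w₂ⱼ cos(ω tⱼ) / Σⱼ w₀ⱼ cos(ω tⱼ) rather than −ω² (for embed = 3
this is −4 sin²(ωτ/2)/τ², the discrete second-difference response).
This closed form is the oracle for the parameter-recovery tests and
bounds the tolerances used downstream: fitted frequency coefficients
are attenuated toward zero, more strongly for fast oscillations and
large lags, so fitted periods are mildly overestimated. This bias is a
property of the published estimator and is reproduced, not corrected.

## Per-dyad fitting and the embedding grid

For each dyad the two partner equations are stacked into one OLS system
with partner-indicator coding and no constant term (the series are
detrended and mean-removed): partner A's rows regress the GLLA
acceleration of A on (x0_A, x1_A, x0_B, x1_B), partner B's rows
symmetrically, giving 8 coefficients per dyad. Fit quality is the
adjusted R² of the stacked system, 1 − (1 − R²)(N − 1)/(N − 9) with N
the stacked row count and R² uncentered (no intercept in the model).
All six combinations of tau ∈ {3, 4} × embed ∈ {3, 4, 5} are fit with
both partners embedded identically (required for aligned rows), and the
combination maximizing adjusted R² is kept; exact ties break to the
smaller embed, then the smaller tau (parsimony). Cells whose embedding
leaves fewer than 5 rows per partner are infeasible and skipped.

Two estimator facts worth knowing when reading fit statistics:

* **Null R² is far from zero.** The GLLA position, velocity, and
  acceleration estimates are linear contrasts of the *same* embedded
  rows, so the acceleration is partly predictable from the position
  even for white noise: at embed = 3 the population uncentered R² under
  independent white-noise partners is exactly 2/3. Adjusted R² values
  should therefore be compared against this inflated baseline, not
  against zero.
* **Identifiability needs spectral richness.** If both partners are
  pure sinusoids at one shared frequency, the eight predictors span
  only a two-dimensional function space per equation and the stacked
  design is rank-deficient. Damping, noise, or distinct frequencies
  restore identifiability; the fitter rejects rank-deficient designs
  explicitly.

## Latent profiles

The 8 coefficients are z-scored across dyads (they differ by orders of
magnitude between frequency and damping roles) and clustered with a
diagonal-covariance Gaussian mixture — latent profile analysis — using
20 random EM restarts, a 1e-6 variance floor, and a fixed seed.
Solution selection deliberately avoids fit statistics: candidate
solutions (k ∈ {2, 3, 4} by default) are screened for profiles holding
fewer than 10% of dyads, and separation is summarized by the mean
maximal responsibility and the minimum pairwise Mahalanobis distance
between profile means. The final k is a recorded configuration
decision. Downstream models use hard modal assignments.

Profile-typical trajectories are rendered by back-transforming each
profile's mean coefficient vector to the raw scale and integrating the
coupled system by fixed-step RK4 from profile-average initial
conditions (or a 50-ms default start); explosive trajectories are
truncated at a divergence limit and flagged. Because person labels
within a dyad are arbitrary (0/1), which partner damps within a profile
is not identified; trajectories are reported per arbitrary label.

## Stage-2 Bayesian models

Two families, both reported with posterior means and 90%
highest-density intervals (shortest sorted-window interval):

* **Outcome models.** Person-level outcome = intercept + profile
  contrasts (+ condition main effects and profile × condition
  interactions when requested) + dyad-varying intercept + residual.
  The dyad intercepts are marginalized analytically — each dyad's two
  observations are bivariate normal with an exchangeable covariance —
  so the sampler only explores the fixed effects and the two scales.
  Profile contrasts are treatment-coded against the largest profile.
* **Profile-membership models.** Multinomial logit of dyad-level
  profile membership on one covariate at a time, decomposed into the
  dyad average (between-dyad variation) and the absolute within-dyad
  difference (the absolute value is forced by the arbitrary 0/1
  labels: a signed difference would have arbitrary sign). Condition
  enters as a four-level factor with optional interactions. The
  reference category is the largest profile.

Priors are flat on regression coefficients and half-Student-t(3,
2.5·sd(y)) on scales. Posteriors are sampled with an affine-invariant
ensemble sampler; walkers are grouped into the configured number of
chains (default 4 chains × 2,000 iterations, first half discarded) for
split R-hat and effective-sample-size diagnostics. Any R-hat ≥ 1.1
triggers one escalation to 10 chains × 10,000 iterations; the final
status is recorded on the summary.

Numerical guards: the residual scale has a relative floor of
1e-4·sd(y) — when the two persons of every dyad agree exactly the
marginal likelihood grows without bound as the residual scale shrinks
and the posterior would be improper; the floor keeps such degenerate
fits finite and is invisible for real data. Scale parameters are
sampled on the log scale with the Jacobian included and reported on the
natural scale.

## The synthetic-data generator

The generator exists so that every stage is testable without access to
restricted study data. It emulates a 65-dyad study: 150 samples per
person (5 min at 2-s windows), a balanced 2×2 between-dyad design
(talking vs. no-talking × cooperative vs. competitive), and three
dynamic regimes drawn with proportions (0.42, 0.26, 0.32):

* `slow_inphase_damping` — period ≈ 45–50 samples, in-phase, one
  partner damping (zeta_self_A = −0.02);
* `fast_inphase_damping` — period ≈ 14 samples, in-phase, one partner
  damping strongly (−0.05), positive position coupling;
* `fast_antiphase` — period ≈ 13–15 samples, opposite-sign initial
  positions with negative position coupling (−0.04), one partner mildly
  amplifying (+0.008), i.e. less stable over time.

Series are integrated by fixed-step RK4 at the sampling step (for this
linear system RK4 equals the degree-4 Taylor expansion of the matrix
exponential; accuracy vs. the analytic sinusoid is better than 1e-3
relative amplitude over 150 samples). A baseline of 800 ms, oscillation
amplitudes of ~50 ms, independent Gaussian sampling noise of 10 ms, and
an optional linear trend give plausible adult IBI series; each dyad's
coefficients are jittered by ±10% uniform so profiles have within-group
variance. Regime labels are drawn from a multinomial-logit model whose
linear predictor can include planted log-odds on covariate dyad
averages and differences (and on condition cells), enabling calibration
and power studies with known ground truth.

What the generator does **not** emulate: respiratory and movement
artifacts, ectopic beats, non-stationary frequency drift, skewed IBI
distributions, and any dependence of noise on the signal. Passing tests
therefore demonstrate that the estimation machinery recovers the model
family it assumes at realistic scales — not that real IBI series follow
this model.

## Problem sizes used in the validation suite

Monte-Carlo suites use 65–200 dyads with 150-sample series for the
estimation checks, 100 replicates for recovery curves, 200 replicates
for the white-noise null, and 25 replicates for stage-2 calibration and
power at reduced sampler budgets (4 chains × 1,600 iterations,
escalating to 6 × 4,000). These sizes make the whole suite run in a few
minutes while keeping binomial bounds meaningful; they are validation
choices, not model defaults.

## Known limitations

* Per-dyad OLS ignores uncertainty in the GLLA derivative estimates;
  no standard errors are produced for the 8 coefficients (they feed a
  mixture model, not hypothesis tests).
* The adjusted R² of the stacked system inherits the null inflation
  described above.
* Oscillation periods are reported from the biased frequency
  coefficient; they are comparable across dyads fitted with the same
  grid but are not unbiased spectral estimates.
* With 65 dyads and 8 indicators, mixture solutions can be sensitive
  to standardization and restarts; the selection report exists
  precisely because no automatic criterion is trusted at this scale.
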