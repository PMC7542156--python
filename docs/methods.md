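# Methods

This document records the mathematical definitions, algorithmic choices,
and known limitations of `sibdetect`. Everything stated here is either a
definition implemented in the code or a property pinned by the test suite;
no empirical claims are made beyond what the seeded examples compute.

## 1. Signal model and preprocessing

Input is tri-axial wrist acceleration sampled at 60 Hz with a binary
per-sample SIB annotation. Preprocessing (`preprocess.py`):

- **Filtering.** 4th-order Butterworth low-pass at 20 Hz, applied causally
  (`scipy.signal.sosfilt`). The cutoff must lie below the Nyquist
  frequency; DC gain is unity. Raw samples are retained alongside the
  filtered ones — the nonlinear battery runs on filtered data, but raw
  windows remain available.
- **Windowing.** 2-second windows advanced in 1-second steps (120 samples,
  50% overlap). A session of n samples yields `(n - 120) // 60 + 1`
  windows; sessions shorter than one window are rejected.
- **Labeling.** Presence rule: a window is positive if *any* of its
  samples is annotated as SIB.

## 2. Features (96 per window)

Per axis (x, y, z) — 19 time-domain, 4 frequency-domain, and 9 nonlinear
features; 3 × 32 = 96.

### 2.1 Time domain (19 × 3)

Cross-axis features use the cyclic pairing x→(x,y), y→(y,z), z→(z,x):
Pearson correlation and mean difference of the pair. Per-axis: variance,
counts of strict interior local minima/maxima, maximum, minimum, seven
percentiles (1, 10, 25, 50, 75, 90, 99; linear interpolation), number of
mean-crossings (sign changes of the mean-centered signal, zeros skipped),
mean, mean absolute value, root mean square, and mean absolute first
difference scaled by the sampling rate ("jerk").

A numerical note on the correlation: a constant channel must yield 0, not
NaN. Constancy is judged *relative* to the channel magnitude (SD ≤ 1e-12 ×
max|value|), because the floating-point mean of n copies of a constant is
not exactly that constant, leaving round-off variance of order 1e-33.

### 2.2 Frequency domain (4 × 3)

Real FFT of the mean-removed window; candidate peaks are strict local
maxima of the magnitude spectrum (DC excluded). The two largest peaks are
reported as (frequency, amplitude) pairs, with amplitude scaled by 2/n so
a unit sine reports amplitude ≈ 1. Missing peaks (e.g. constant windows)
report 0 for both members of the pair.

### 2.3 Nonlinear dynamics (9 × 3)

All computed on the delay embedding with **τ = 5 samples and M = 4**,
giving K = N − (M−1)τ = 105 embedded vectors per 120-sample window. The
module also ships the standard selection diagnostics — first strict local
minimum of the binned average mutual information (16 bins) and the 1/e
crossing of the autocorrelation for τ; global false nearest neighbors for
M — used to justify the fixed values, not to adapt them per window.

**False nearest neighbors** uses Kennel's dual criterion: the nearest
neighbor of a point in dimension m is false if the added (m+1)-th
coordinate separates the pair relatively (ratio > R_tol = 15) or absolutely
(augmented distance > A_tol = 2 standard deviations). The ratio test alone
cannot satisfy both canonical behaviors — a noiseless periodic signal
settling at small M and white noise staying flagged at the maximal M —
because exact recurrences make the ratio blow up on float dust while
sparse high-dimensional sampling deflates it. Exact recurrences
(separation below 1e-10 SD) count as true neighbors.

**Sample entropy** SaEn(M, r, N) = −ln(φ^{M+1}(r) / φ^M(r)) with
r = 0.2 × SD of the window. φ^m averages, over all N−m+1 templates of
length m, the fraction of *other* templates within Chebyshev distance r
(self-matches excluded, normalization by n_templates − 1). A constant
window returns 0; zero matches at length M+1 return +inf, which the
feature table caps at the out-of-band sentinel 10.0. At M = 4 on
2-second noise windows the sentinel is common — this is informative
(high irregularity), not an error.

**Cross-sample entropy** measures asynchrony between two axes. Both
series are standardized, and each template of one series is compared only
to the **time-aligned** template of the other (Chebyshev distance,
r = 0.2 on the standardized scale): cross-SaEn = −ln(φ_{M+1} / φ_M) with
φ_m the fraction of aligned pairs within r. This synchronous definition —
rather than the all-pairs variant — is what makes identical streams give
exactly 0 and the statistic exactly symmetric; low values mean the two
axes move with the same waveform at the same time. Zero aligned matches
give +inf, capped at 10.0 in the feature table.

**RQA.** Euclidean distance matrix of the embedded vectors; the radius is
chosen as the quantile of off-Theiler-band distances targeting 1%
recurrence, with a bisection fallback, and the realized recurrence rate is
verified inside the 0.1–2% band (degenerate windows where no radius can
achieve this are flagged and report zeroed RQA features). Theiler window
w = 1; minimal line length 2 for both diagonal and vertical structures.
Reported: recurrence rate, determinism (fraction of recurrent points on
diagonal lines ≥ 2), laminarity (vertical analogue), maximal diagonal
length, divergence (its reciprocal), and trapping time (mean vertical
line length ≥ 2).

**DFA** (first order). Profile = cumulative sum of the mean-removed
series; 12 log-spaced box sizes in [4, N/4]; boxes tiled from both ends;
per-box linear detrend; α is the slope of log F(s) vs log s. White noise
gives α ≈ 0.5, its integral α ≈ 1.5, and a linear ramp saturates at
α ≈ 2 (the ramp's profile is quadratic — this is a well-defined answer,
not a failure). Only genuinely degenerate inputs (constant series, zero
profile) are flagged; flagged windows report the neutral value 0.5 in the
feature table.

## 3. Dimension reduction

**Lasso stage** (`LassoSelector`): features are standardized; an
L1-penalized logistic path is fit over 40 penalties log-spaced from
λ_max (the smallest penalty that zeroes all coefficients, computed from
the score at the null model) down to λ_max × 1e-4. Ten-fold stratified CV
scores each penalty by mean deviance (2 × log-loss); the selected penalty
is the **largest** one whose mean deviance is within one standard error
of the minimum (the "1-SE rule", favoring sparsity). Features with
nonzero coefficients at the refit survive. λ relates to scikit-learn's
C by C = 1/(nλ). λ = 0 reproduces unpenalized logistic regression.

**PCA stage** (`PCAReducer`): selected features are standardized;
components are kept up to the smallest count reaching 65% cumulative
explained variance (or a fixed count when configured). Zero-variance
columns are dropped with a warning. Sign convention: the
largest-magnitude loading of each component is positive, making runs
comparable. The `prompt` indicator (whether a window followed a task
demand) bypasses PCA and is carried as metadata.

## 4. Multilevel logistic regression

For window i of participant j with component scores X:

    P(Y_ij = 1) = logit⁻¹(α_j + Σ_k β_jk X_ijk)
    α_j ~ N(γ₀, σ_α²),   β_jk ~ N(γ_k, σ_k²),  independent.

The marginal likelihood integrates the participant effects out. The
integral is approximated by the **Laplace method**: for each participant
the integrand is maximized over the random-effect vector by damped Newton
iterations (the penalized log-likelihood is strictly concave), and the
Gaussian curvature correction −½ log det(ZᵀWZ + D⁻¹) − Σ log σ applied.
The fixed effects γ and log-standard-deviations are then maximized
jointly by L-BFGS-B, warm-starting each participant's mode and bounding
log σ in [log 1e-3, log 10]; an estimate at the lower bound is reported
as zero. Reported per-participant coefficients are posterior modes.

Inference: Wald tests from the numerically differentiated observed
information for the fixed effects; for each variance component, a
likelihood-ratio test against the model with that component pinned at
zero, referred to the boundary-corrected ½χ²₀ + ½χ²₁ mixture. Confidence
intervals for the standard deviations are Wald intervals on the log scale,
exponentiated. A single-participant dataset (no between-participant
information) falls back to pooled logistic regression with a warning.

The comparison bank (`make_model`) covers nine group-level kinds — the
multilevel model, varying-intercept-only, plain logistic, forward-stepwise
logistic with two-way interactions selected by BIC, k-NN, linear / cubic /
Gaussian SVM, decision tree — plus per-participant logistic fits.

## 5. Evaluation protocol

- **Split**: 80/20, stratified jointly by participant *and* class, so
  every participant contributes training rows (required for participant
  random effects). The held-out pool is evaluated twice: as-is
  (natural class ratio) and undersampled to equality (balanced).
- **Balancing**: training uses seeded random undersampling of the
  majority class to exact equality.
- **Cross-validation**: stratified 10-fold on the (balanced) training
  pool; the fold count is halved when the minority class is too small.
- **Metrics**: accuracy, specificity, precision, recall, F-score
  (harmonic mean of precision and recall). Zero-denominator ratios report
  0 with a flag instead of NaN. A pseudo-R² (squared correlation of
  outcome with fitted probability, adjusted as
  1 − (1 − R²)(n − 1)/(n − p − 1)) and wall-clock training/prediction
  times per observation are recorded; timing is never asserted.

## 6. Synthetic data generators

`generate_session` builds per-participant sessions: background activity is
1/f ("pink") noise via FFT spectral shaping plus a slow 0.1 Hz drift;
SIB episodes arrive with Poisson-distributed counts at the configured rate
(durations uniform in a configured range, non-overlapping by rejection),
and each episode superimposes an amplitude-enveloped sinusoid at the
participant's characteristic frequency with jittered phase and amplitude,
concentrated on one axis with attenuated leakage into the others. Labels
mark episode samples exactly. Child seeds are derived deterministically
from the cohort seed.

`generate_multilevel_features` draws directly from the multilevel logistic
model above (X ~ N(0,1)) for estimator-recovery studies with known ground
truth.

**Realism limits.** The generator produces caricatures, not clinical
data: real SIB is less stationary, less sinusoidal, and far less separable
from background than these bursts; real background activity contains
non-SIB rhythmic movement (clapping, rocking) that this generator omits;
annotation timing error, sensor drift, and gravity orientation changes are
not modeled. Consequently, classifier metrics on synthetic cohorts are
plumbing checks and upper bounds, not estimates of field performance.
Published figures from real cohorts cannot be reproduced from this
package, because no real data ships with it.

## 7. Numerical conventions

- Sample/cross-sample entropy: +inf sentinels capped at 10.0 in feature
  tables; constant series → 0.
- DFA: flagged (degenerate) windows → neutral 0.5 in feature tables.
- RQA failure to reach the recurrence band → zeroed RQA features for that
  window (flag recorded by the battery).
- Logistic sigmoid computed via tanh, log(1+e^x) via `logaddexp` — both
  overflow-safe.
- Unpenalized logistic fits use `LogisticRegression(C=np.inf)`.
- All stochastic steps (generation, balancing, splits, CV shuffling,
  tree/SVM seeds) are driven by explicit integer seeds; `run_pipeline` is
  bit-reproducible given its config, timing columns excepted.

## 8. Limitations

- The Laplace approximation biases variance components slightly downward
  in small groups; the test suite checks interval *coverage* on planted
  simulations rather than asserting unbiasedness.
- Fixed τ = 5, M = 4 follows the published analysis choice; per-window
  adaptive embedding is available but unused in the pipeline.
- The stepwise-BIC model's search is greedy and can miss interactions
  that only help jointly.
- The natural-ratio test set inherits whatever prevalence the synthetic
  cohort produced; it matches deployment skew only as far as the
  configured episode rates do.
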