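# Methods

`imukit` derives quantitative movement biomarkers from wearable inertial
sensor (IMU) recordings of three rhythmic clinical tasks used in the
assessment of cerebellar ataxia — finger-nose-finger (FNF), fast alternating
hand movements (AHM) and heel-shin (HS) — and uses them to estimate disease
status and severity on the Brief Ataxia Rating Scale (BARS).  This note
documents the models, the defaults and the reasoning behind the open design
choices.

## Preprocessing

Each recording is a tri-axial accelerometer + gyroscope stream at 128 Hz
from the wrist (FNF, AHM) or ankle (HS) sensor.  Because sensor orientation
is arbitrary, each modality is reduced to the projection onto its first
principal component, computed on the full recording (task and rest halves
together).  The PCA sign is unidentifiable; we fix it by making the
largest-magnitude loading component positive.  Power-based features are
sign-robust, but the AR-HMM is not, so the convention is mandatory.

Recordings are split at their temporal midpoint into a *task* half (the
instrumented side performs) and a *rest* half (the other side performs); the
half with the larger sum of per-sample gyroscope vector norms is labeled
task, with ties going to the first half.  This is the simplest construction
that divides the recording into equal portions by total velocity magnitude.

For the AR-HMM observation sequence both projections are additionally

1. wavelet denoised: multilevel Symlets-4 decomposition at the maximum depth
   the length permits, symmetric padding, soft thresholding of *all* detail
   coefficients at the absolute threshold 0.04;
2. downsampled by 10 with a zero-phase FIR anti-alias filter (naive striding
   would alias tremor bands into the model's range), giving 12.8 Hz;

and stacked into a T' x 2 array (accel-PC1, gyro-PC1).  Denoising precedes
downsampling.  Preprocessing contains no randomness.

## Time-frequency features

The synchrosqueezed wavelet transform (SST) is a continuous wavelet
transform with an analytic bump wavelet (Fourier profile
exp(1 − 1/(1 − ((ξ−μ)/σ)²)) on |ξ−μ| < σ, with μ = 5, σ = 0.6), whose
coefficients are reallocated along the frequency axis to their instantaneous
frequency.  We estimate the instantaneous frequency from the wrapped phase
increment of the analytic coefficients — the discrete form of the phase
transform Im[∂_b W / W]/2π — and accumulate |W|² into the frequency bin
nearest the estimate on a grid of 32 voices per octave over [0.1, 15] Hz.
Energy reallocated above 15 Hz is discarded; coefficients with negligible
magnitude keep their own scale's center frequency.  Signals are
reflect-padded to a power of two before the FFT; power is the squared
magnitude, so all power features scale quadratically with signal amplitude
and center frequencies are scale-invariant.

Sixteen features are computed per (task, side, modality) from the task-half
and rest-half transforms (computed on the halves separately, to avoid
smearing across the split): total power, task/rest power ratio, band powers
below/above the task cutoff (2 Hz for FNF/HS, 3 Hz for AHM; half-open bins
[lo, hi) avoid double counting), low/high ratios, power-weighted center
frequencies, unnormalized frequency spreads, band-restricted center
frequencies (task half), and the mean cosine similarity of adjacent
time-bin power columns.  3 tasks x 2 sides x 2 modalities x 16 = 192
features per session.  Ratios with zero denominators return NaN sentinels,
imputed at modeling time with the training-fold finite column maximum
(random forests need finite values; fold-local imputation avoids leakage).

## Sticky AR-HMM

Latent states x_t follow a Markov chain; given x_t = k, the observation is

y_t ~ MVN(A^(k) [y_{t−1}; …; y_{t−n}], Σ^(k)),     n = 5 lags (0.4 s).

The transition prior is the weak-limit truncation of a sticky HDP-HMM at
L = 5 states: β ~ Dir(γ/L · 1), π_i· ~ Dir(αβ + κδ_i), with rows of π
indexing the source state.  Each (A, Σ) has a matrix-normal inverse-Wishart
prior: Σ ~ IW(ν₀ = 5, S₀ = 0.01·I), A | Σ matrix-normal centered at
M₀ = 0.25·1_{2×2n} with row covariance Σ and column precision
K₀ = diag(linspace(5, 100)) — distant lags are shrunk harder.  No per-state
bias term is modeled.

α = γ = κ = 20 calibrates the prior so simulated latent runs center around
100–200 ms: on 30 s intervals at 12.8 Hz the pooled median run is 156.25 ms,
consistent with the analytic check E[π_ii] = (α/L + κ)/(α + κ) = 0.6, whose
geometric-run median is 2 steps = 156.25 ms.  `sample_prior_predictive`
reproduces this and is the package's headline calibration quantity.

Inference is blocked Gibbs sampling:

- **States**: forward filtering–backward sampling under the AR likelihoods.
  The forward pass runs in linear space with per-step normalization after a
  per-time max-shift of the log-likelihoods (equivalent to log-space message
  passing).  The AR likelihood contributes from t = n on; the first n states
  are governed by the transition structure alone from a uniform
  initialization, which avoids inventing an initial-observation density.
- **Transitions**: rows of π are conjugate Dirichlet updates; β is resampled
  with the standard weak-limit auxiliary-variable scheme (Chinese-restaurant
  table counts per transition cell, self-transition tables thinned at the
  stickiness odds ρ = κ/(α+κ), then β ~ Dir(γ/L + column table sums)).
- **Dynamics**: per-state conjugate MNIW updates from the time points
  assigned to the state (each y_t regressed on its n stacked lags, t ≥ n);
  states with no assigned points draw from the prior.

Sampling is staged.  **Stage 1** learns (A, Σ) by full sweeps over a small
training subset — one recording per task for four subjects spanning the
severity range (one control, three ataxic) — with 2000 draws, burn-in 100.
Label mode-switching is a known hazard when averaging draws of
mixture-type models, so posterior means use draws in (burn, truncate];
`truncate_at` defaults to 1000, and a running-mean jump diagnostic on β is
reported but never auto-applied.  **Stage 2** fixes the posterior-mean
dynamics and infers states and (β, π) per recording (200 draws, burn-in 50,
150 retained), initialized globally at the stage-1 posterior means.
All samplers take explicit seeds and are reproducible bit-exactly.

From each stage-2 inference, 27 features: per state, the mode frequency,
posterior-mean self-transition probability, mean and population sd of mode
run lengths (in 12.8 Hz steps; milliseconds appear only in prior-predictive
reporting), and the mode concentration (fraction of draws equal to the mode,
averaged over that state's mode time points); plus the entropy rate of the
posterior-mean transition matrix (base-2 logarithm, bits per step; stationary
distribution from the leading left eigenvector, falling back to the
empirical mode frequencies for reducible chains) and the overall fraction
of draws matching the mode.  Per-time-point mode ties break toward the
lowest state index.  3 tasks x 2 sides x 27 = 162 features per session.

## Classification and regression

Diagnosis classification uses a balanced random forest: 200 trees, each
grown on a bootstrap in which every class is resampled (with replacement)
down to the minority-class size.  This is implemented in-package over
scikit-learn decision trees, with each tree's bootstrap retained so tests
can audit the exact class balance.  Severity regression uses a 200-tree
random forest with maximum depth 10 and the mean-absolute-error criterion,
trained on control (score 0) and ataxia sessions; sessions missing a target
score are dropped per target.

All evaluation is leave-one-subject-out: every session of one subject is
held out per fold.  AUROC is computed on pooled out-of-fold probabilities
(standard for LOSO, where folds hold one subject); sensitivity/specificity
threshold the positive-class probability at 0.5.  Three-class problems
report accuracy and a confusion matrix.  Regression reports pooled Pearson
r, r² and MAE.  Test–retest reliability correlates first- versus
second-session out-of-fold scores across subjects with repeat visits
(sessions beyond the second are ignored).

## Synthetic cohort generator

Clinical IMU data of this kind is not publicly distributable, so the
package ships a generator that emulates the statistical structure the
analysis assumes; it is first-class, tested code.  Each recording is a
quasi-periodic oscillation at the task fundamental (FNF 1 Hz, AHM 2.5 Hz,
HS 0.75 Hz — all below the band cutoffs) along a uniformly random rotated
axis (fresh per recording, so the PCA step is exercised every time), with
an active and a rest half (40/10/20 s per side for FNF/AHM/HS) and
per-channel sensor noise (sd 0.05).

Severity, on a BARS-total-like 0–30 scale, perturbs exactly the properties
the features measure — since ataxia affects the rhythmicity and speed of
action, the generator adds (i) a tremor above the cutoff (default 4 Hz)
with amplitude 0.03 per severity unit (half amplitude during rest), and
(ii) Brownian phase jitter of the fundamental with per-sample increment sd
0.005·severity.  The mapping is linear by construction; the slopes are
fixed defaults chosen so that a severity-20 subject's tremor is a clearly
visible ~0.6-amplitude component against a unit-amplitude fundamental.
Parkinsonism instead gets a 5 Hz rest-half tremor (a textbook choice) and
carries no BARS scores.  Ataxia severities are uniform on [1, 20];
a configurable fraction of subjects receive a second session with severity
perturbed by N(0, 1).  Limb subscores are noisy rescalings of the total.
One master seed expands to per-recording child streams through documented
`SeedSequence` spawn keys, so cohorts are bit-reproducible and any subset
can be regenerated independently.

The generator does **not** emulate biomechanics, gravity components,
magnetometer channels, sensor drift, or the heterogeneity of real patient
movement; passing tests therefore demonstrate the pipeline's internal
correctness and its sensitivity to severity-linked rhythmicity degradation,
not clinical performance.  Real-data accuracies cannot be reproduced from
synthetic cohorts and are out of scope.

## Numerical choices and problem sizes

- Degenerate inputs: constant signals raise a degenerate-signal error in
  PCA; zero-power transforms yield NaN feature sentinels; absent states
  yield (0, 0) run statistics; non-finite likelihoods raise a numerical
  failure carrying the time index.
- The forward filter flags all-zero messages instead of dividing by zero.
- MNIW posterior scale matrices are symmetrized before sampling.
- Test and example runs use a reduced Gibbs schedule (stage 1: 200 draws,
  burn 20, truncate 100) and cohorts of up to 40 subjects; the production
  defaults (2000/100/1000) are the package configuration defaults.  The
  package's own validation sizes — 10,000-draw prior moment checks,
  50,000-point OLS cross-checks, 2,000-point state-recovery runs, 3,000-sweep
  Geweke chains — were chosen to make Monte-Carlo error small against the
  asserted tolerances.

## Known limitations

- Stage-1 posterior means average raw draws; if a label mode-switch occurs
  inside the retained window the means blur across states.  The β-trace
  diagnostic surfaces this but relabeling is not attempted.
- The truncated (L = 5) model does not learn the number of states; the
  nonparametric L → ∞ extension is out of scope.
- The SST frequency grid starts at 0.1 Hz; slower trends alias into the
  lowest bins.
- Balanced undersampling uses within-class bootstraps of minority size;
  exactly reproducing other balanced-forest implementations' tie-breaking
  is not attempted.
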