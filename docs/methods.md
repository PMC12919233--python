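# Methods

## The model

`crossarea` analyses simultaneous population recordings from two cortical
areas — a premotor-like area A (PMd analog) and a somatosensory-like area B
(Area 2 analog) — during a reach-to-grasp (R2G) pellet-retrieval task.  The
core is a delayed two-area Gaussian-process factor model.  Per trial and
20-ms time bin,

    y_A(t) = C_A [x_cf^A(t); x_wf^A(t)] + d_A + eps_A,  eps_A ~ N(0, diag R_A)
    y_B(t) = C_B [x_cf^B(t); x_wf^B(t)] + d_B + eps_B,

where each latent is a zero-mean, unit-variance Gaussian process with the
squared-exponential kernel

    k(dt) = (1 - sigma_n) exp(-dt^2 / (2 tau^2)) + sigma_n delta(dt).

A *cross-area factor* (CF) is a single GP observed by both areas; the
area-B view runs on a time axis shifted by a per-factor delay D (positive:
area B follows area A).  The white floor sigma_n = 1e-3 is independent
between the two views, so the cross-view covariance carries only the
smooth term.  *Within-area factors* (WFs) exist in one area only.  Unit
latent variance fixes the scale indeterminacy; loadings carry amplitude.
Factor counts default to 5 CFs + 5 WFs per area, matching the dimension
convention the analysis standardizes on for cross-session comparability.

### Fitting

Loadings, offsets and noise variances are updated by the standard
closed-form EM step.  The E-step computes the exact joint-Gaussian
posterior over all latents of a trial in precision form: with K the prior
Gram (block-diagonal by factor; 2T x 2T blocks for CFs) and
G = C' R^-1 C the per-bin observation information, the posterior precision
is K^-1 + I_T (x) G, factorized once per iteration and shared across
trials of equal length.

Timescales and delays are *not* updated by maximizing the expected
complete-data log-likelihood (the textbook M-step).  That update is
heavily damped: with sigma_n = 1e-3 the prior correlation between the two
CF views is 0.999, the posterior inherits the current delay almost
exactly, and in practice delays move on the order of 1 ms per hundred
iterations from their 0 init.  Instead each latent's (log tau, D) is
updated by conditionally maximizing the *marginal* likelihood with
everything else fixed (an ECME-type step).  This is cheap because the
rest of the model acts on latent j as correlated observation noise whose
information matrix is recoverable from quantities the E-step already
produced:

    W_j = Sigma_jj^-1 - K_j^-1,        h_i = Sigma_jj^-1 mu_ij,

with Sigma_jj the posterior covariance block and mu_ij the posterior
means of latent j.  The conditional log-likelihood of a candidate kernel
K(theta) is then, up to a constant,

    -2 ll(theta) = n [logdet K + logdet(K^-1 + W_j)]
                   - sum_i h_i' (K^-1 + W_j)^-1 h_i,

an O((2T)^3) computation per evaluation, optimized by L-BFGS-B in
log(tau) with box bounds tau in [10, 1000] ms and D in [-250, 250] ms
(the delay coordinate is pre-scaled by 100 so the optimizer's default
finite-difference step is meaningful).  With this step, delays converge
in ~20-40 EM iterations on synthetic sessions.  Because the per-latent
conditional steps are applied in parallel from one shared posterior, a
joint overshoot is possible in principle; the fitter therefore monitors
the marginal log-likelihood and, on any decrease beyond the convergence
tolerance, reverts the kernel parameters and substitutes the
guaranteed-monotone Q-function update for that iteration.  The recorded
`fit_log` is non-decreasing to 1e-6 relative tolerance.

Initialization is deterministic and data-driven: CF loadings from the SVD
of the lag-zero cross-covariance between areas (a probabilistic-CCA-style
init), WF loadings from the top eigenvectors of each area's residual
covariance, noise from marginal residual variances, tau = 100 ms, delays
= 0.  Degenerate noise estimates are floored at 1e-4 of the channel
variance.  After fitting, factors are ordered within group by descending
loading power and signed so the peak of the trial-averaged trace is
positive — a deterministic stand-in for qualitative grouping.

### Variance accounted for

Per area, a factor group's VAF is the variance of its posterior
reconstruction (loadings x posterior latents) as a percentage of the
offset-removed data variance; the residual is defined as the remainder
(observation noise plus cross-terms), so CF + WF + residual = 100 by
construction.  The PCA baseline (`pca.fit_pca`) runs on trial-concatenated
bins x channels and reports per-PC VAF; PCA input is smoothed with a 40-ms
Gaussian kernel to give it the temporal prior the GP model has built in.

## Preprocessing

Spiking path: spike counts in half-open 20-ms bins over a 2-s window
centered on pellet touch (spikes exactly at the window end excluded);
channels below a 1-Hz session-wide rate are dropped (0.5 Hz is the
documented relaxed setting for degraded arrays); then per-channel rate
normalization, square-root transform, optional Gaussian smoothing (40 ms
for the PCA/decoding path, none for the factor-model path), per-channel
demeaning and z-scoring over all trial bins.  Demeaning subtracts the
scalar per-channel mean, not the per-bin PSTH — subtracting the PSTH
would null the trial-averaged latent structure the model is meant to
capture.  The transform order is recorded in `normalization_state` and
enforced.

Spiking-band power (SBP) path: broadband voltage at 1017.25 Hz is
high-pass filtered at 240 Hz (5th-order Butterworth, applied
forward-backward — the zero-phase choice avoids latency distortion, at
the cost of non-causality that is irrelevant offline), median-subtracted
per bank of 16 channels, z-scored, then a multitaper spectrogram with
20-ms bins and windows (time-bandwidth product 2, 3 DPSS tapers — the
smallest standard choice stable at 20-sample windows) is averaged over
300-500 Hz.  The band is configurable; 300-500 Hz is the default.

## Behavior and kinematics

Wrist speed is the frame-to-frame Euclidean displacement of each of three
redundant tracked wrist points, averaged over available points and
smoothed with a 5-sample Gaussian kernel; hand aperture is the distance
between the thumb and index positions, each the mean of two redundant
palmar points.  Coordinates stay in pixels (no camera calibration);
decoding targets are unit-free after z-scoring.  Missing samples with
gaps of at most 3 frames are linearly interpolated; longer gaps stay
missing and are excluded from decoding.  Pose CSVs in the DeepLabCut
dialect are accepted with a likelihood threshold of 0.9 (configurable;
the threshold is a package choice, not an asserted constant).

Trial matching keeps first-attempt successful trials whose reach-to-touch
and touch-to-retract durations are within a tolerance (0.1 s for
stereotypy, 0.2 s for trial averaging) of the session medians.  Time
warping rescales the pre-touch and post-touch segments linearly onto the
median durations, holds t = 0 (touch) fixed, and carries samples outside
[reach onset, retract] rigidly; a trial already at the medians passes
through bitwise.

Epoch modulation flags channels whose trial-averaged z-scored trace
leaves +/-1 SD anywhere in the window (task modulated) or within a 200-ms
epoch: pre-reach (-500..-300 ms before reach onset), reach (+/-100 ms
around reach onset), grasp (-50..+150 ms around touch), retract
(0..200 ms after retract onset).

Session phases: "Early" = first two post-lesion sessions with more than
five rewarded trials; "Late" = sessions whose trial-duration distribution
is not significantly different from the pre-lesion baseline.  "Not
significantly different" is operationalized as a two-sided rank-sum test
at alpha = 0.05.  Normalized R2G duration = session median trial duration
/ baseline median.

## Reliability metrics

- `stereotypy_position`: per trial, Pearson correlation of the warped
  single-trial factor trace against the mean trace of all other matched
  trials (exact leave-one-out, not a grand-mean approximation), over the
  reach-onset -> retract span; session value = median over trials;
  undefined (not zero) with fewer than 3 matched trials.
- `consistency_velocity`: per trial, |v_i - mean_j v_j| where v is the
  first difference of the factor trace at the bin nearest a behavioral
  timepoint (reach onset, touch, retract; ties toward the earlier bin);
  the factor's reported timepoint is the one with the lowest median
  absolute deviation; all successful trials enter (the metric is
  duration-agnostic).  A "grasp mean" reduction (mean of the touch and
  retract deviations) is available as an alternative.

Both are computed on the CF's area-A view by default; the area-B view is
a config switch.  Stereotypy is invariant to affine rescaling of a trace;
consistency scales with trace amplitude, so cross-session comparisons
assume z-scored inputs.

## Decoding and statistics

Kinematic targets are interpolated linearly from the 50-fps frame grid to
bin centers (no extrapolation).  Predictors are time-lagged duplicates of
each factor at lags 0, -60, -120, -180 ms.  Decoding is ordinary least
squares with repeated hold-out validation: 30 random 80/20 splits at the
bin level — timepoints are the unit being held out — scoring the
coefficient of determination on the held-out bins.  Whole-trial hold-out
is available (`split_unit="trial"`) for leakage-sensitive analyses.
Predictor families are compared by Kruskal-Wallis omnibus on session
medians with pairwise two-sided rank-sum post-hocs gated at p < 0.05.
Recovery trends use Spearman correlation (all animals) or a linear
mixed-effects model with an animal-specific random intercept (recovery
animals; delegated to statsmodels MixedLM).

## The synthetic generator

The generator emulates the study's recordings so the pipeline is testable
end to end without data access.  Defaults mirror the study conditions:
two areas of 40 channels, 80 trials, 2-s epochs at 20-ms bins centered on
touch; 5 CFs with tau = (60, 100, 140, 180, 200) ms and a +30 ms area-B
delay; 5 WF_A at 120 ms and 5 WF_B at 40 ms (bracketing the reported
timescale ordering CF > WF_PMd > WF_Area2); events at -450 ms (reach
onset) and +300 ms (retract) with +/-40 ms uniform jitter.

Each latent is drawn as `sqrt(1 - j^2) * template + j * deviation`, both
GP draws with the latent's kernel: the session-level template models
event-locked task structure, and the trial jitter j in (0, 1] sets
trial-to-trial reliability without changing the marginal variance.  CF
views are drawn jointly on the union of the bin grid and its
delay-shifted copy, so on-grid delays make area B an exact shifted copy
of area A.  Observations are loadings x latents + Gaussian noise,
converted to spikes by rectified-linear rate modulation around a 20-Hz
base rate (multiunit-like) and Poisson sampling — chosen so the
square-root transform downstream approximately variance-stabilizes.
The optional voltage path emits broadband noise plus a 300-400 Hz
carrier whose envelope follows the loading-weighted latents, giving SBP
bins a known relation to the latents.  Wrist speed and aperture are
linear CF readouts plus noise at a 3:1 amplitude SNR, embedded in tracked
point coordinates so that the kinematics module's own derivations recover
them.  Kinematic traces are clipped to physical ranges (speed >= 0),
a mild nonlinearity the decoding analyses tolerate.

The recovery series ramps only CF parameters (all CF tau to a schedule
value, CF jitter down, nominal trial durations down); WF parameters stay
fixed, so any WF trend found downstream is spurious by construction.
Session seeds derive deterministically from the master seed and session
index.

What the generator does *not* emulate: non-Poisson spiking statistics,
electrode drift and unit turnover, behavioral failure modes (all trials
succeed on the first attempt by default), nonlinear latent-to-kinematics
maps, and non-stationarity within a session.  Passing tests therefore
demonstrate correctness of the pipeline under the model's own
assumptions, not robustness to real-data pathologies.

## Problem sizes and numerical choices

Test-suite fits run at reduced scale chosen for a single-CPU run: the
parameter-recovery check uses the full study scale (40 channels/area, 80
trials, 20-ms bins) with the EM cap reduced to 60 iterations (relative
tolerance 1e-6), which suffices for timescale and delay-sign recovery;
the ordering and recovery-series checks use 40-ms bins, 20 channels/area
and 40 trials with caps of 25 and 16 iterations.  Posterior solves use
Cholesky factorization throughout; kernel Grams carry the 1e-3 white
floor plus a 1e-10 jitter where a draw requires a factorization.
Zero-variance channels are dropped; empty selections raise rather than
return empty results.

## Known limitations

- Delay identifiability degrades as tau grows (a 30-ms delay under a
  200-ms kernel shifts the cross-covariance peak by a fraction of its
  width); the weakest-loading CF's delay sign is the least reliable.
- Factors within a group are exchangeable at initialization; EM
  differentiates them via their kernels, but with few iterations latent
  mixtures remain (visible as off-diagonal correlation against ground
  truth).
- The conditional-ML kernel step is exact only with other parameters
  fixed; its parallel application across latents is a heuristic with a
  monotonicity guard, not a proof.
- Mixed-effects trend tests use a random intercept only (no random
  slope), matching the small number of animals the design anticipates.
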