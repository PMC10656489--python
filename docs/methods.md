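# Methods

This note records the models implemented, the choices made where the design
was open, and what the synthetic data do and do not establish.

## Obstacle-avoidance dynamics

Trajectories follow a first-order attractor `xdot = f(x) = gain (x* - x)`
(straight obstacle-free reaches with smooth slowdown; `gain` = 1 s^-1),
modulated near a convex obstacle by `M(x) = E D E^-1`. `E`'s first column is
the outward normal of `Gamma(x; s) = sum_i ((x_i - c_i)/(s a_i))^(2 p_i)`;
the eigenvalues are `lambda_n = 1 - Gamma^{-1/rho}` for the normal direction
and — the remaining eigenvalues being unconstrained by the construction —
`lambda_t = 1 + Gamma^{-1/rho}` for *all* d-1 tangent directions, the
standard symmetric choice for this modulation family. With equal tangent
eigenvalues `M v = lambda_t v + (lambda_n - lambda_t)(n·v) n`, so no
tangent basis is needed during integration; `basis_matrix` still exposes the
explicit orthonormal `E` (QR completion of the normal) for analysis.

* **Workspace defaults**: start (-0.5, 0, 0) m, target (0.5, 0, 0) m, a
  vertical ellipsoid (`a = (0.12, 0.12, 0.20)` m, `p = (1, 1, 1)`) at the
  origin — a reach over a table past a centrally placed object. All
  configurable.
* **Integration**: fixed-step explicit Euler, `dt = 2 ms`, stop within 1 mm
  of the target or after 20 000 steps. The step size keeps the worst-case
  discrete penetration of the inflated boundary below the 1e-3 tolerance in
  `Gamma` units (tangent steps along a curved isoline cut the corner by
  ~`h^2/2r`); the step budget covers the slow normal-direction approach to
  the attractor at high reactivity (the modulation scales the approach rate
  by `lambda_n` ≈ 0.2–0.3 near the target for `rho = 8`). Integration is
  fully deterministic.
* **Head-on saddle**: a start exactly on the obstacle-target axis is a
  (measure-zero but default) saddle of the modulated field. A deterministic
  tangential kick (1% of speed, applied only when the tangential fraction is
  < 1e-6 and `Gamma` < 1e4) resolves it reproducibly; far-field behavior is
  untouched.
* **Costs**: energy efficiency is the travelled path length (sum of step
  lengths); comfort is the minimum clearance to the *uninflated* obstacle
  surface, measured along the ray to the obstacle center (closed form for
  ellipsoids, vectorised bisection otherwise; a distance-to-center dialect is
  available). Interrupted trials are scored on the complete simulated path
  for their (rho, s) — the observer is modelled as judging the predicted
  full movement.
* **Start variability**: each trial's start pose receives isotropic Gaussian
  jitter (SD 3 cm), emulating trial-to-trial variability in where a repeated
  back-and-forth reach begins. Beyond realism this matters statistically:
  with a perfectly fixed geometry the deterministic (rho, s) → (efficiency,
  comfort) map is nearly one-dimensional (the two costs co-vary almost
  perfectly along a curve), and no estimator could identify a subject's
  two-dimensional cost weighting from it. Execution variability restores the
  two-dimensional support that real robot data possess.

## Synthetic subjects and EEG

* **Behavior**: `P(release) = sigmoid((w_e·eff + w_c·comf + bias)/T)`.
  Cohorts draw criterion directions spread over 10–80 degrees in the cost
  plane (magnitude 60, temperature 0.5) — subjects genuinely differ — and
  per-subject rejection rates from N(27%, 7%) clipped to [10%, 45%],
  matched by quantile calibration of the bias on each subject's own cost
  ensemble. Release latencies are truncated Gaussians (mean 1.08 s,
  SD 0.14 s). `T -> 0` gives a deterministic (noiseless) criterion.
* **EEG**: 16 channels (Fz…CP4) at 512 Hz. Background is AR(1)-colored
  Gaussian noise (coefficient 0.95, stationary SD `noise_sd`, default 8 uV)
  with a uniform inter-channel correlation of 0.5 from a shared common
  source — volume conduction makes neighbouring EEG channels share most of
  their background, and without it the any-channel artifact-rejection rule
  over-fires (see below). The model still has no 1/f + alpha-peak structure
  and no non-stationarity. Rejected trials add `errp_gain` times a
  template: negative Gaussian half-wave at 0 s (SD 40 ms), positive at
  0.25 s (SD 60 ms), plus hann-windowed theta (6 Hz, [-0.1, 0.4] s) and mu
  (10 Hz, [-0.1, 0.1] s) bursts with per-trial random phase, all scaled by
  a cosine-tapered frontocentral profile peaking at FCz. The uV scale is a
  free parameter of the generator; the default (5.5 uV against 8 uV noise)
  is calibrated so the cohort-mean single-trial decoding AUC sits at ≈ 0.86,
  the operating regime of ErrP decoders in this task family that all
  downstream analyses presuppose.
* **Calibration**: 90 s in three 30-s segments (eye rolling, saccades,
  repeated blinking at ~0.75-s intervals; source amplitudes 100–300 uV)
  mixed into the EEG channels by a known (stored) 3×16 matrix, plus 2 uV
  of EOG sensor noise.
* **Artifacts**: a chosen fraction of epochs is scaled by a gross amplitude
  factor, ground truth retained.

Passing tests on these data demonstrate that the *pipeline machinery* is
correct and well-calibrated under its own generative assumptions; they do
not establish performance on recorded EEG, whose noise is richer in every
respect listed above.

## Preprocessing

Filter order mirrors acquisition practice: 50-Hz notch, then a zero-phase
second-order Butterworth high-pass at 1 Hz (scipy `sosfiltfilt`, reflective
padding), then EOG regression with `b = Cov(EOG,EOG)^-1 Cov(EOG,EEG)` from
the calibration recording (ridge fallback for singular autocovariances),
then epoching at [-0.2, 0.6] s around the onset (the release time on
erroneous trials; the subject's mean release time on correct ones).
Erroneous trials with reaction times below 0.5 s or beyond half the trial
are dropped. Artifact rejection computes, per channel, a fixed-bin
histogram density (100 bins over the pooled min–max, machine-epsilon
flooring of empty bins) of all epoch amplitudes; the per-trial joint log
probability is thresholded at mean + 3 SD per channel, and a trial is
rejected if *any* channel exceeds its threshold. The estimator (histogram,
bin count, per-channel thresholding without z-scoring) is a documented
choice; alternatives are configurable.

## Time-frequency analysis

The S-transform is evaluated as an exact linear convolution of
`x(t) e^{-2 i pi f t}` with the frequency-scaled Gaussian
`|f|/sqrt(2 pi) e^{-t^2 f^2/2}` (FFT-based), at 1-Hz steps over 1–30 Hz;
the f = 0 row is the signal mean by convention. Direct numerical quadrature
of the defining integral is kept in the test suite as an independent oracle
(agreement < 1e-6). ERSP uses average *power* |S|^2 across trials
(magnitude is a configurable dialect) with a channel-specific baseline
mu(f), the mean correct-trial power over [-0.1, 0.4] s.

## Decoding

All fitting happens inside training folds of a stratified, seeded 10-fold
split: the CCA spatial filter (trials concatenated in time against their
class-mean templates; first three canonical channel-weight vectors; tiny
ridge on the covariances for rank safety), the min–max feature
normalisation, and the LDA. Features are the three component amplitudes
decimated to 64 Hz (the 16-Hz zero-phase low-pass guarantees anti-aliasing)
concatenated with Welch PSDs (one Hann segment of up to 256 samples, 50%
overlap) read at 4–16 Hz in 2-Hz steps — 3·32 + 3·7 = 117 features. The
LDA's binary posterior is exactly the sigmoid of its linear score, and the
binary output thresholds it at 0.5. No shrinkage by default (the SVD solver
tolerates ill-conditioned folds); a shrinkage flag exists.

## Criteria inference

Criteria maps bin trials into a 40×40 grid whose edges always come from the
simulated ensemble min–max; empty cells stay NaN. Criterion fits are
effectively unregularised logistic regressions (C = 1e6, standardised
internally for conditioning only; coefficients are mapped back to the raw
scale). The transfer analysis trains one two-covariate classifier per
subject and label source (behavior, or the decoder's 0.5-thresholded
output); intra-subject accuracy is 10-fold cross-validated, inter-subject
accuracy is the arithmetic mean of the trained classifier's accuracy on the
16 other subjects — in both conditions scored against *behavior*, since the
question is how well the inferred criterion predicts what the person did.
The 2×2 repeated-measures ANOVA (label source × transfer) is computed from
within-subject sums of squares, each effect tested against its own
effect-by-subject interaction (no sphericity correction is needed for
two-level factors; degenerate all-equal inputs return F = 0, p = 1 rather
than 0/0). Map similarity is the Pearson correlation over jointly occupied
cells of a behavioral and an inferred map (pairs with < 3 shared cells are
skipped); the per-subject intra value is compared with the mean of its
inter values by Wilcoxon signed-rank.

## Problem sizes

The cohort analyses use 17 subjects × 400 trials — the study scale — with
the decoder cross-validated per subject; the trajectory battery uses 200
random (rho, s) draws; the artifact operating point uses 10 seeds × 400
epochs; the decoder ladder 5 gain levels × 3 seeds. The boundary-recovery
check reports the mean relative slope error over three noiseless subjects
with different criterion angles; a single subject's error at 400 separable
trials has an irreducible margin-geometry scatter of a few percent, so the
subject-mean is the stable quantity.

## Known limitations

* The AR(1) background makes decoding somewhat easier than on real EEG;
  absolute AUCs transfer only qualitatively.
* The per-channel joint-log-probability statistic is approximately a sum of
  squares and therefore right-skewed, so its mean + 3 SD tail holds more
  than the Gaussian 0.13% per channel; OR-ing over 16 channels, the rule
  spuriously rejects ~10% of clean synthetic trials (vs ~2% under a
  Gaussian-tail expectation). Inter-channel background correlation reduces
  but does not eliminate this; on real recordings shared artifacts correlate
  the per-channel statistics much more strongly, which is why the same rule
  operates at a few percent there.
* Efficiency and comfort remain strongly correlated even with start jitter
  (as they are in any fixed-workspace design); one-covariate fits therefore
  predict behavior nearly as well as the two-covariate criterion.
* The eigenvalue construction modulates the field at any distance for large
  reactivity (`Gamma^{-1/rho}` decays slowly in `Gamma`), so far-field
  straight-line behavior holds for low reactivity only — this is a property
  of the model, not of the implementation.
* No online/asynchronous decoding, no cross-subject transfer of EEG
  features, no inverse reinforcement learning over trajectory features.
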