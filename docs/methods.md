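# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## The cosine phase-behavior model

The core model regresses a behavioral measure on instantaneous oscillatory
phase,

    y_i = A·cos(θ_i + τ) + B + ξ_i,    τ ∈ [0, π],

and defines the phase-utility on behavior (PUB) as |A|.  The fit is solved
exactly by linearizing the shifted cosine into `a·cosθ + b·sinθ + B`
(`a = A·cosτ`, `b = −A·sinτ`) and solving one ordinary least-squares
problem; |A| = √(a²+b²) and τ = atan2(−b, a), with a negative sign absorbed
into A so τ stays in [0, π].  This is preferred over a nonlinear search for
exactness and because the statistic is evaluated over large grids (channels ×
frequencies × time points × participants); a brute-force τ-grid solver exists
in the test suite as an independent oracle and agrees to ≤10⁻⁶ relative
residual.

Conventions and edge cases:

- Phases live in (−π, π], matching the range of the four-quadrant
  arctangent that produces them.
- At τ = π the parameterizations (A, π) and (−A, 0) describe the same curve;
  the solver may return either, so downstream code should rely on |A|, the
  predicted curve, or the optimal phase — all of which are unique.
- The optimal (fastest-reaction-time) phase is π − τ for A > 0 and −τ for
  A < 0; the accuracy-maximising phase is the antipode.
- The model is only identified when trial phases cover the circle.  Each fit
  carries an ill-conditioning flag, raised when the mean resultant length of
  the phases is ≥ 0.9 or a Rayleigh test rejects uniformity at α = 0.01.
  Under severe locking the estimate is not asserted to shrink to zero (the
  linear system is simply ill conditioned); the flag, not a numerical claim,
  is the contract.
- For accuracy, trials are binned into 8 equal-width phase bins on (−π, π]
  (right-closed) and per-bin accuracy is regressed on the bin-center phases,
  unweighted.  Empty bins raise an error rather than being merged silently;
  callers can request fewer bins.
- Reaction times enter as log₁₀(RT in ms); incorrect trials are included by
  default (the fit benefits more from trial count than it loses to
  error-trial noise), with a `correct_only` option.

A comparison index, the weighted circular mean (1/N)·Σ r_i·e^{iθ_i} with
behavior min-max scaled to [0, 1], is provided.  Its modulus tracks phase
dependence under uniform phases but inflates under phase locking regardless
of behavior — the failure mode that motivates the PUB plus its locking flag.

## Time-frequency decomposition

Complex Morlet wavelets with constant frequency-to-bandwidth ratio
f/σ_f = 7; σ_t = ratio/(2πf).  The default analysis grid is 50
logarithmically spaced frequencies from 1 to 60 Hz.  Numerical choices the
formula itself does not fix:

- Kernel truncation at ±4 σ_t (envelope < 3.4·10⁻⁴ of peak there).
- FFT-based convolution with zero padding, output aligned to the input
  samples; a direct-summation oracle bounds the error at 10⁻⁸.
- Samples within 2 σ_t of either signal end are flagged unreliable.  Note
  the zero-padding bias at exactly 2 σ_t is still ~2% in amplitude; the <1%
  power-flatness guarantee for pure tones holds beyond ~4 σ_t from the
  edges.
- Zero convolution magnitude yields −inf log-power and a masked phase.

Epoching extracts phase around speech onset on a 100 Hz grid over the
closed window [−2.0 s, +1.5 s] — 351 points.  Extraction is nearest-sample
from the full-rate decomposition; this is the "downsampling" of the phase
maps, so no additional filtering touches the phase.  Whole-session
decomposition (for the EEG-fMRI power regressors) and segmented
decomposition share the same operation.

## Preprocessing

All operations are linear.  Ocular correction regresses each channel jointly on
the VEOG and HEOG series (with intercept) and subtracts only the EOG
contribution — the standard regression reading; channels orthogonal to the
EOG span are untouched.  Average re-referencing subtracts the instantaneous
scalp mean (a projection, hence idempotent).  Periodic artifacts
(scanner/cardiac) are removed by subtracting the mean event-locked template
over fixed windows; overlapping windows are rejected because they would mix
artifact instances.  Downsampling uses a zero-phase FIR anti-alias filter —
zero-phase is mandatory here because any phase distortion would bias the PUB
— and requires an integer rate ratio.

## Group inference

Per participant, the surrogate PUB at every grid point is the **median** of
200 PUBs computed after permuting the behavior vector across trials (phases
fixed; permutation without replacement, one permutation shared across grid
points per repetition; a bootstrap option exists but is off by default).
The median is used because |A| has a right-skewed null distribution.  Two
properties follow and matter for interpretation:

- A single permuted draw is exchangeable with the original PUB under the
  null; the median-of-200 aggregate is a low-variance estimate of the null
  median, *not* a draw from the original's distribution.
- The original-vs-surrogate t-map therefore has a small positive offset
  under the null (null mean of |A| exceeds its median).  The max-statistic
  permutation calibration absorbs this: measured family-wise error over 200
  null cohorts is at or below the nominal 0.05 (conservative).

Pointwise two-sample pooled-variance t-maps (positive t = PUB above
surrogate) are thresholded one-sided at p < 0.001 (sidedness is a config
flag; the alternative hypothesis is directional).  Suprathreshold points are
clustered by adjacency — ±1 time step, ±1 frequency step, or neighboring
electrode — and clusters spanning fewer than 2 distinct electrodes are
excluded as lacking spatial expansion.  Electrode neighborhoods come from a
distance rule (closer than 1.4 × median nearest-neighbor distance; 1.4 keeps
lattice diagonals out) and can be replaced by template neighbor lists.
Cluster significance uses the maximum retained-cluster summed-t statistic
over 10,000 permutations in which the 2N pooled grids are randomly re-divided
into two groups of N (a within-participant sign-flip scheme is available but
is not the reference procedure); p-values use the +1 correction.  The same
extent exclusion is applied inside the permutation null for consistency.

Leave-one-participant-out selection recomputes the t-map from N−1
participants, forms clusters at p < 0.01 (no extent exclusion at this stage
— extent filtering is a group-level decision), and matches each group
cluster to the CV cluster with maximal member overlap (ties: overlap
fraction, then cluster mass).  Matched members are restricted to the group
cluster's bounding region (its electrode set and time-frequency bounding
box) — an automated, deterministic stand-in for matching clusters by eye —
and the maximum-t point is selected.  Participants with no overlapping CV
cluster are flagged missing and dropped from the ANOVA (how such
participants should be imputed is genuinely open; dropping is the
conservative choice).

The phase-binned analysis rotates six equal sextants of the circle so each
participant's own optimal phase sits at the center of bin 1, averages
log-RT per bin, and runs a one-way repeated-measures ANOVA
(df = (5, 5(N−1)); with 14 participants, (5, 65)).  The closed-form ANOVA
assumes sphericity; it is cross-checked against an independent
implementation in the tests.

## EEG-informed fMRI GLM

Band-limited power (electrode-set mean on the linear scale at the nearest
log-grid frequency bin) is z-transformed per session, convolved with the
canonical HRF, and sampled at scan times.  The HRF is a double gamma
parameterized by its landmarks — response peak 6 s, undershoot peak 16 s,
peak:undershoot ratio 6, 32 s support, peak-normalized (gamma shape =
peak + 1 at unit scale, so the mode lands exactly on the landmark); all
parameters are config-exposed.  The voxelwise model Y = Xβ + ε (EEG
regressor(s), task boxcar regressor, six head-motion nuisance columns,
intercept) is fitted by OLS per participant; group inference is a
random-effects one-sample t-test on the per-participant β.  Multiple-testing
correction beyond an optional Benjamini–Hochberg helper is out of scope, as
is all spatial preprocessing: the module consumes voxels × scans matrices.

## Synthetic data: what it emulates, what it does not

The generator reproduces the study conditions the analysis is designed for:

- **Task timing**: speech onset exactly 2.0 s after masking-noise onset,
  noise offset 1.5 s after speech onset, ~1 s spoken word, probe after the
  word, inter-trial gap drawn uniformly from
  {1.167, 1.262, 1.357, 1.452, 1.547, 1.642, 1.737, 1.833} s.  The probe
  duration used for layout is a fixed nominal 1.2 s (the scale of typical
  mean reaction times); simulated RTs do not feed back into the timing.
- **Behavior**: log₁₀RT = B + A·cos(θ+τ) + N(0, sd); responses slower than
  2 s recorded as null.  Defaults A = 0.05, τ = 1.0, B = 3.05, sd = 0.12
  give ~1.1–1.2 s mean RTs, ~98% response rates (≈300 usable trials of 306)
  and, with accuracy_base = 0.75, ~75% accuracy — the regime of a
  speech-in-noise task near threshold.  The single-trial RT dispersion is
  not something the analysis pins down a priori; sd = 0.12 (≈ ±32% RT
  spread) was fixed once from pilot simulation as a realistic value and the
  pilot effect size A = 0.05 makes the group test clearly but not trivially
  powered.
- **EEG**: 30-channel (configurable) layouts on the unit disc with 10-20
  names; per-channel 1/f background (exponent 1.0 — no noise model is
  canonical, so the exponent is a parameter); a locus oscillation whose
  phase at the locus time is re-drawn uniformly per trial, so the PUB's
  uniformity precondition holds by construction (a continuous oscillator
  would risk phase-locking to the regular trial grid).  The oscillation also
  reaches the locus channel's montage neighbors at 60% amplitude, as volume
  conduction would — without spatial spread no effect could ever survive
  the ≥2-electrode cluster rule.  Null studies (A = 0) carry no
  distinguished channel at all.
- **BOLD**: active voxels are β·(HRF ⊛ z-power) sampled at TR = 2 s plus
  Gaussian noise; null voxels are pure noise.  333-volume sessions minus
  three discarded volumes give the 330-scan default.

Master seeds split into per-participant child seeds by a documented
arithmetic rule (`child = master·1000003 + 7919·k + 1 mod 2³¹`), so any
participant can be regenerated alone and all generators are deterministic
given their arguments.

What it does **not** emulate: acoustic stimuli, real scalp topographies or
anatomically realistic volume conduction, non-stationary or correlated noise
across channels, MR gradient and ballistocardiogram artifacts beyond a
simple periodic template, behavioral learning or fatigue drifts.  Passing
tests therefore demonstrate the *statistical machinery* — exact recovery in
the model family, calibrated error rates, localization at a known effect —
not robustness to every physiological confound of real recordings.

### Pipeline simulations on the reduced grid

Whole-pipeline calibration and power studies (family-wise error over 200
cohorts, localization over 50) run on a reduced grid — 8 electrodes × 5
frequencies × 20 time points, 14 participants × 306 trials, 200 surrogate
repetitions, 1000 permutations — and sample epoched phase directly on the
analysis grid (`gen_phase_field`: per-trial random-phase oscillators, which
is exactly what the raw-EEG → wavelet → epoch path produces at the grid
points, as the unit tests verify once).  These sizes are the package's
standard simulation conditions; they preserve every structural ingredient of
the inference (adjacency, spectral/temporal coherence, trial-phase
uniformity) at roughly three orders of magnitude less computation than
rerunning the wavelet path per replicate.  Because a phase-field oscillator
is coherent across the epoch, an injected effect extends along the full time
axis; localization claims therefore concern channel and frequency, with the
locus time fixed by the anchor convention.

## Known limitations

- The pooled two-group permutation scheme treats the original and surrogate
  grids as exchangeable units; it is conservative (measured FWE ≈ 0 at
  nominal 0.05) rather than exact, a direct consequence of the
  median-aggregated surrogate's reduced variance.
- The accuracy variant of the PUB is substantially less powered than the RT
  variant (8 binned observations per fit) and has no surrogate path in the
  CLI.
- Degenerate designs (phase-locked trials, zero-variance regressors,
  zero within-participant ANOVA error) are flagged or rejected, never
  silently repaired.
- BrainVision files are read (via mne) but not written; the native
  interchange format is a float32 matrix with a JSON header.
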