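# Methods

This note documents the models, numerical choices, and known limitations
of the `fittsfusion` pipeline: what the synthetic generator emulates, how
each metric is computed, and which design decisions were genuinely open.

## Task model

A trial is a point-to-point reach to a target of width *W* at distance *D*,
with index of difficulty ID = log2(2*D*/*W*) bits. The default design is
14 subjects × 6 conditions (*W* = 5 mm; *D* = 10, 20, 40, 80, 180, 320 mm)
× 5 repetitions, organized as randomized blocks in which every condition
appears once per block. The resulting difficulty levels are
{2, 3, 4, 5, log2(72) ≈ 6.170, 7} bits: the 180 mm condition is *not* an
integer number of bits, and the generator reports the computed value
rather than forcing 6.0, staying faithful to the printed geometry.

Movement time is sampled as MT = *a* + *b*·ID + ε with defaults
*a* = 0.35 s, *b* = 0.22 s/bit, ε ~ N(0, 0.15² s²), plus a per-subject
N(0, 0.08²) intercept offset; draws are floored at 0.1 s. The intercept and
slope are not reported by the study this emulates; the defaults are chosen
once from the typical range for stylus/haptic pointing (total MT ≈ 0.8–1.9 s
across the design) and give a pooled MT–ID correlation near 0.9.

## Synthetic channel models

The generator is phenomenological: it reproduces the *statistical
structure* the analysis assumes (which metric responds to difficulty, how
strongly, with what heterogeneity), not the biophysics of each signal.

* **Trajectory** (default 100 Hz, configurable; the acquisition rate of the
  haptic device is not published): a minimum-jerk backbone
  p(τ) = p₀ + (p_f − p₀)(10τ³ − 15τ⁴ + 6τ⁵) plus a zero-mean perturbation
  orthogonal to the reach axis — Gaussian noise low-passed at 3 Hz,
  windowed by sin(πτ) so the endpoints stay exact, with amplitude
  0.6·(1 + 0.35·ID) mm times a log-normal subject factor. Straightness
  (PathStrDev) therefore degrades with ID. Path *efficiency* (path length /
  straight distance) falls with ID under the defaults, because the extra
  arc length contributed by a roughly constant-frequency wiggle grows much
  more slowly than the straight-line distance (which doubles per bit); this
  reproduces the negative efficiency–difficulty correlation such studies
  report while keeping the literal length-ratio definition. Raising the
  amplitude growth rate flips the sign, so either reading can be emulated.
* **Limb IMUs** (100 Hz): the forearm tracks the (perturbed) tool path
  scaled by 0.9, the upper arm by 0.45, each with a log-normal subject
  factor and a 5 % per-trial jitter. Angular velocity is tangential speed
  over a 0.35 m effective arm length on one gyro axis; acceleration is the
  second derivative of limb position with gravity on z. Sensor noise is
  low-passed (8 Hz) Gaussian: 0.01 rad/s (gyro) and 0.0025 m/s²
  (accelerometer — the in-band noise of a Shimmer-class MEMS part).
  Deriving the IMU from the perturbed trajectory makes corrective
  submovements carry into limb jerk, which is what makes jerk rise with
  difficulty; the smooth backbone alone (jerk ∝ D/MT³) is nearly flat in
  ID at short distances.
* **EMG** (1024 Hz): band-limited (20–450 Hz) Gaussian carrier shaped by
  the reach speed profile over a tonic floor, normalized so the whole-trial
  RMS equals activation × MVIC, activation = (0.05 + slope·ID) with slope
  0.020 (pectoralis major) / 0.016 (posterior deltoid), times log-normal
  subject (σ = 0.25) and trial (σ = 0.15) factors. Pooled feature–ID
  correlations land near 0.55, matching the moderate EMG correlations the
  screen expects.
* **GSR** (512 Hz): tonic level 2 μS plus a half-sine drift whose max–min
  range is (0.4 + 0.10·ID) × the subject's baseline range × log-normal
  trial noise (σ = 0.45).
* **PPG** (512 Hz): Gaussian systolic pulses with mean interval 60/HR,
  HR = resting HR × (1 + 0.012·ID + N(0, 0.05)), 2 % beat jitter, and a
  0.33 s minimum interval (≈180 bpm cap). GSR and PPG traces span
  MT + 4 s — the reach plus surrounding rest — because a sub-second trial
  cannot contain the two pulse peaks heart-rate extraction needs;
  trajectory, IMU, and EMG traces span exactly MT.
* **EEG states**: the five cognitive-state probabilities are emitted
  directly as clipped affine-in-ID values plus noise (the classifier that
  produces them from raw EEG is proprietary and out of scope). Engagement
  and Workload get small positive slopes (population r ≈ 0.25);
  Distraction, SleepOnset, and HeadMvL get near-zero slopes so a 0.20
  screen typically excludes exactly those three. Because Engagement and
  Workload sit deliberately close to the threshold, individual replicates
  occasionally drop one of them — the screen is honest about sampling
  variability.

One master seed drives everything through `numpy.random.SeedSequence`
children keyed by (subject), and (subject, block, slot), so any subset of
the design regenerates identically and a dataset is a pure function of
(config, seed).

## Feature extraction

* **EMG conditioning**: linear-phase FIR band-pass 20–450 Hz (Hamming
  design, ~10 Hz transition, ≥40 dB stopband) and a second-order IIR 60 Hz
  notch, both applied forward–backward (zero phase), then mean removal.
  The notch uses Q = 10: a narrower notch rings for hundreds of samples at
  the trace edges, which sub-second trials cannot afford, while Q = 10
  still leaves a 100 Hz tone within 1 % mid-trace.
* **Weighted MAV**: (1/N)Σ wᵢ|xᵢ| with wᵢ = 1 on the middle half of the
  window, the ramp 4i/N on the first quarter, and the *symmetric* ramp
  4(N−i)/N on the last quarter. The trailing branch is sometimes printed
  as 4(i−N)/N, which is negative for i > 0.75N; a weighting function must
  be a non-negative taper, so the symmetric form is the default and the
  printed form is available behind `printed_weights=True`. In the
  continuous limit the weights integrate to 0.75.
* **EMG RMS**: rectify, 2 ms edge-replicating moving average, then the
  quadratic mean of the smoothed envelope over the whole trial. The
  ordering rectify → smooth → RMS uses each stated element of the
  definition exactly once; windows shorter than 2 samples (or at least as
  long as the trace) are degenerate and skipped. MVIC normalization is
  applied to the final scalar.
* **SCvr**: max–min range of the 5 Hz zero-phase low-passed conductance
  trace divided by the subject's baseline-session range (the same max–min
  statistic applied to the baseline recording).
* **Heart rate**: systolic peaks on an 8 Hz low-passed envelope with a
  0.33 s minimum spacing and a relative prominence floor; HR = 60 / mean
  peak-to-peak interval, divided by resting HR. Fewer than two detectable
  peaks is an error, not a silent zero.
* **Path metrics**: PathStrDev averages the perpendicular distance
  ‖p₀pᵢ × a‖/‖a‖ over i = 1…n (the start point is the reference and is
  excluded; the endpoint contributes its identically-zero deviation,
  matching the summation range of the definition). PathEff is total path
  length over straight-line distance, ≥ 1 by the triangle inequality.
* **Derivatives**: third (trajectory jerk) and first (IMU jerk)
  derivatives use Savitzky–Golay local-polynomial filters, polyorder 5,
  ~0.15 s windows. SG filters differentiate and low-pass in one step and
  are exact for polynomial trajectories up to the polyorder *including at
  the boundaries*, where plain central differences after IIR smoothing
  lose accuracy on short traces; the minimum-jerk oracle (jerk RMS =
  √720 for a unit reach in unit time) is reproduced to ~0.1 %. Jerk RMS is
  a trapezoidal time average so the extreme endpoint values are not
  double-weighted. Limb jerk is computed as the derivative of
  gravity-removed acceleration (the IMU measures acceleration, not
  position — same third-derivative quantity, one integration level up).
* **Gravity removal**: the per-axis trial mean (gravity plus static bias
  under an approximately constant limb orientation) is subtracted before
  taking acceleration magnitudes; the result is invariant to any constant
  offset vector. No orientation fusion is attempted — none is reported for
  the emulated setup, and short single-reach trials give a quaternion
  filter little to work with.

## Screening and normalization

Pearson correlations are pooled across all subjects and repetitions
(420 rows), as the emulated analysis states; this ignores within-subject
dependence (pseudo-replication), which is a property of the original
protocol, not a bug of the implementation. Categories are assigned on
|r| — a strongly negative correlate (path efficiency) is as informative
as a positive one. p-values are reported per metric without
multiple-testing correction, matching the emulated analysis; a
Benjamini–Hochberg adjustment can be applied downstream by the user if
desired. z-scores use the population (1/n) standard deviation — the
definition does not specify n vs n−1 and either is internally consistent;
population SD is the convention fixed here. In cross-validation the
z-score parameters are estimated on each training fold and applied to its
test fold by default (leakage-safe); `standardization="global"` normalizes
once before splitting for literal replication of a
normalize-then-cross-validate protocol.

## PLS regression and evaluation

The PLS-1 core follows NIPALS: for a univariate response the inner
iteration converges in a single pass (w ∝ Xᵀy is already the
covariance-maximizing direction), so each component is extracted directly,
X and y are deflated by the rank-one part, and coefficients for every
truncation 1…A come from B = W(PᵀW)⁻¹q. Centering is part of the
algorithm and always uses the training fold's means, even when the columns
were scaled globally. At the full component count on full-rank data the
fit equals ordinary least squares (verified to 1e-8 against a direct
solve), and score vectors are mutually orthogonal by construction;
scikit-learn's `PLSRegression` serves as an independent oracle in the
tests, never as the implementation.

The number of latent components is chosen per outer training fold by inner
5-fold CV RMSE (the emulated analysis does not state a component count),
with ties — including the all-machine-epsilon ties of exact-fit data —
broken toward fewer components; a fixed count can be configured instead.
Rank-deficient folds are fitted with as many components as the data
supports.

Outer CV uses k = 10 folds stratified by difficulty level, so every fold
contains all six conditions and per-fold R² is well defined; fold
assignment is seeded, and the six criteria (R², RMSE, MAE, NRMSE, NMAE,
MAPE) are averaged over folds with equal weight. NRMSE and NMAE divide by
the maximum observed response — 7 bits for the full design — which is the
convention that makes a published summary of this form internally
consistent (e.g. 0.666/7 = 0.095); the RMSE radical carries the 1/n
factor, the only reading under which the normalized and unnormalized
columns of such a summary agree. Percent improvement of model *m* over the
movement-time baseline is 100·(RMSE_I − RMSE_m)/RMSE_I.

## What passing tests do and do not show

The generator's defaults were calibrated once so the *structure* of the
screen matches the emulated study — kinematic metrics strongest, EMG and
autonomic metrics moderate, three EEG states excluded — and the model
comparison on synthetic data reproduces the qualitative ordering
fusion ≥ kinematic > movement-time > physiological. The synthetic data are
far cleaner than real recordings: no electrode lift-off, motion artifact,
or missing beats; channel noise is Gaussian and stationary; subject
effects are log-normal and independent across metric families; EEG states
are generated directly rather than classified from raw signals. Passing
tests therefore demonstrate the correctness and stability of the
*pipeline* — extractors against closed-form oracles, PLS against OLS and
an independent implementation, CV bookkeeping, determinism — not that the
specific published effect sizes would be recovered from new human data.

Problem sizes used by the test suite: the full 420-trial design for
bookkeeping and screening checks, 20 independent full-design replicates
for the stochastic recovery and model-ordering properties, and an
8-trial miniature design for fast unit and round-trip tests.

## Known limitations

* No haptic/VR rendering, force feedback, or musculoskeletal simulation;
  the virtual-wall constraint appears only as the trajectory's z ≡ 0.
* EEG is pass-through: no spectral analysis or cognitive-state
  classification.
* No repeated-measures or mixed-effects modeling, post-hoc tests, or
  kernel/nonlinear PLS variants.
* The block randomization is uniform per block; counterbalancing schemes
  beyond "randomized, blocked" are not modeled.
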