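# Methods

`arval` re-implements, as a reusable pipeline, the agreement analysis used to
validate a smartphone-based augmented-reality training game (TG) against an
optoelectronic motion-capture reference. The TG logs the pose of a
head-mounted display (HMD) at ~30 Hz in its own world frame; the reference
system records four reflective markers on the HMD at 120 Hz in the lab frame.
The analysis asks one question: how well do the two systems agree, per frame
on the trajectories and per repetition on exercise amplitudes?

## Coordinate conventions

Positions live on the anatomical axes — sagittal (front–back), transversal
(side-to-side), longitudinal (vertical, gravity-aligned) — in millimetres,
right-handed lab frame. Orientation is decomposed with the intrinsic Euler
sequence rotation (longitudinal) → flexion (transversal) → lateral flexion
(sagittal), i.e. scipy's `"ZYX"` with x = sagittal, y = transversal,
z = longitudinal, in degrees. The reference convention used by the original
laboratory software is not public; any consistent convention yields the same
agreement statistics as long as generator and analysis share it, which they
do here. This is also why exact numeric replication of the original rotation
table would be convention-dependent.

## Synthetic study

Real recordings exist but are not required: the generator reproduces the
study conditions so every downstream estimate has a known ground truth.

**Protocol.** Each subject performs two trials. Trial 1 is scripted: five
head nods (the synchronization movement), then 3 squats, 3 side-steps to the
right and back, 3 step-ups, 3 side-steps to the left and back, separated by
1 s rests. Trial 2 is five nods followed by about one minute of free play
(randomized exercise order, seeded). Subject stature is drawn from
N(1750 mm, 100 mm) truncated to [1400, 2100] mm, matching the study
population (175 ± 10 cm).

**Motion primitives.** All movements are raised-cosine pulses — smooth (C¹),
band-limited, with analytically known amplitude. A squat is a downward
longitudinal dip of `squat_depth_frac · height` (default 0.20); a step-up is
a rise–hold–fall plateau of `step_height`; a side-step is an out-and-back
transversal excursion of `sidestep_width` (one repetition per excursion, so
a scripted trial holds 3 + 6 + 3 repetitions). Step and side-step defaults
(200 mm, 300 mm) are values at the reference stature of 1750 mm and scale
linearly with subject height; every repetition also gets a seeded
multiplicative jitter (default 10%). Both choices reflect how humans
actually vary — and without between-repetition variance, correlation-based
agreement statistics (ICC, Spearman) would be undefined. Squats and step-ups
additionally tip the head forward by 0.3 × amplitude on the sagittal axis,
which is biomechanically expected and gives the sagittal channel enough
signal for frame registration to be well conditioned. The nod block is five
flexion oscillations (default 20°) with a small coupled sagittal/longitudinal
translation (1 mm per degree) so that positional cross-correlation can also
lock onto the synchronization movement. The original study reports no
waveform shapes or amplitude magnitudes; these defaults are plausible
magnitudes, not reconstructions.

**Degradation.** The reference recording samples the truth at 120 Hz with
sub-millimetre white position noise (default 0.5 mm), reflecting the
marker-camera system's accuracy. The TG recording samples at 30 Hz, starts
`injected_lag` seconds after the reference clock (default 0.5 s), and reports
in its own world frame: rotated by `frame_rotation` (default 90° about the
vertical — the inertial unit gravity-aligns the vertical axis, so the frames
can differ only horizontally) and displaced by `frame_offset`. Its position
error has two parts:

* white per-frame jitter, `tg_noise_sd` (default 5 mm), and
* a slow wander of the world-frame anchor, modelled as a stationary
  Ornstein–Uhlenbeck process with sd `tg_wander_sd` (default 22 mm) and
  correlation time `tg_wander_tau` (default 2 s).

The split matters. Per-frame trajectory error is set by the total sd
(√(5² + 22²) ≈ 22.6 mm, giving a pooled per-axis MAD of ≈ 18 mm — the
magnitude the original study reports). Per-repetition amplitude error,
however, is governed almost entirely by the slow part: a max-minus-min
amplitude read through heavy white noise acquires a large extreme-value
bias (~3σ), which would put the mean relative difference an order of
magnitude above what validated inertial-plus-vision trackers achieve,
whereas slow wander shifts both extremes together. The white + wander model
reproduces both scales at once. Rotation noise is white (default 0.75°,
giving a rotational MAD of ≈ 0.6°). An optional linear drift term exists but
defaults to zero (the original measurements, ≤ 2.5 min, showed no relevant
drift). All randomness derives from explicit seeds through independent
`SeedSequence` streams; identical configurations are bit-identical.

**What the generator does not emulate.** No whole-body model (only the HMD
trajectory is simulated); no occlusion-driven marker gaps by default; no
heavy-tailed or movement-correlated TG error; no clock drift between the
systems. Passing tests therefore demonstrate that the *analysis chain* is
correct and calibrated under controlled conditions, not that the real
instrument meets any particular accuracy.

## Pipeline

1. **Lag.** Normalized cross-correlation of the mean-removed sync channel
   (default `rot_flexion`, where the nod lives; positional fallback
   available), both streams resampled to the TG rate, searched within ±3 s,
   with parabolic sub-sample refinement of the peak. Positive lag means the
   TG stream is behind the reference. Peak correlation below 0.5 attaches a
   low-confidence warning. Refinements below 1 µs are snapped to the integer
   lag so that identical streams report exactly zero.
2. **Crop.** Both streams are cropped to their common span and linearly
   interpolated onto the TG timestamps (the coarser grid — no detail is
   invented at 120 Hz). Angle channels interpolate on unwrapped values.
3. **Frame.** The TG world frame is registered by the signed axis
   permutation (48 candidates) maximizing the summed per-axis Pearson
   correlation with the reference positions, followed by mean-offset
   removal per axis. Restricting to permutations (rather than free
   rotations) encodes the gravity alignment of the inertial unit; a full
   Procrustes variant is available behind a flag. If the runner-up
   candidate scores within 1% of the winner the alignment is refused as
   ambiguous rather than silently guessed.
4. **Trajectory agreement.** Per-frame absolute differences (TG − reference)
   are pooled across all analyzed trials; MAD is reported as mean ± SD of
   the pooled absolute differences (the SD can exceed the mean, as in the
   original tables) together with RMSE. Per-trial MADs are retained, and a
   trial-1-only aggregation is reported alongside the pooled one.
5. **Repetitions.** With ground-truth segment labels (synthetic runs) the
   repetition intervals are taken from the labels. Label-free segmentation
   detects excursion peaks on each exercise's primary axis — transversal
   for side-steps, longitudinal for squats (down) and step-ups (up) — with
   prominence at least the height-scaled threshold (defaults: squat 0.10,
   step-up 0.07, side-step 0.10 of subject height; minimum repetition
   separation 0.8 s) and extends each interval to the surrounding
   near-baseline crossings (2% of the threshold). Extending only to the
   detection-threshold crossing itself would truncate the excursion and
   systematically underestimate the max-minus-min amplitude, so the
   boundary sits near baseline instead. When several thresholds fire, the
   largest threshold-normalized excursion wins. Amplitude is max − min of
   the primary-axis channel inside the interval, each extremum found
   independently of when it occurs. TG and reference repetitions are
   matched greedily by maximal interval overlap within the same exercise.
6. **Amplitude agreement.** Per exercise: MAD ± SD, RMSE, MARD
   (mean |TG − ref| / ref; zero-reference pairs are excluded with a counted
   warning), Spearman's ρ (average ranks for ties), ICC, and the
   non-parametric Bland–Altman summary. Scripted trials only — free play
   has no protocol to pair against.

## Statistical choices

* **ICC variant.** Two-way random effects, absolute agreement, single
  measure — ICC(2,1) — computed from the two-way ANOVA mean squares, with
  the standard F-based 95% interval (McGraw & Wong case A,1) and the
  F = MSR/MSE test on (n−1, (n−1)(k−1)) df. The original analysis does not
  name its variant; this one is the natural choice for two measurement
  systems treated as random raters, and is pinned here as a documented
  assumption (cross-checked against `pingouin` in the tests).
* **Normality.** Kolmogorov–Smirnov with parameters estimated from the
  sample is anti-conservative under the classical null table, so p-values
  use the Lilliefors construction: a seeded Monte-Carlo null table of the
  statistic (10⁴ standard-normal samples per sample size, cached). The
  add-one p-value estimator `(1 + #{D₀ ≥ D}) / (N + 1)` keeps the test
  valid at finite simulation size.
* **Bland–Altman.** Differences are TG − reference (instrument under test
  minus gold standard). The non-parametric variant is the default: median
  difference, limits of agreement at the 2.5th and 97.5th percentiles under
  the linear-interpolation percentile definition (stated explicitly because
  limits at n ≈ 90–180 are sensitive to it). The parametric ±1.96 SD
  construction is available behind a flag only.
* **Sample size.** Fisher-z two-sided:
  n = ((z₁₋α/2 + z₁₋β)/atanh r)² + 3, rounded to the nearest integer and
  floored at 4 (the smallest n with positive df). Rounding to nearest —
  rather than always up — matches the published calculation for a strong
  correlation (r = 0.5, α = 0.05, β = 0.2 → 29 subjects; the value is 29.01,
  and exact-power calculators also give 29).

## Numerical choices and degenerate inputs

Zero-variance channels raise an explicit error in lag estimation and in the
correlation statistics rather than returning NaN. Constant amplitude columns
make ICC/Spearman undefined and raise. Gaps (frames with fewer than three
visible markers, or collinear visible sets) are flagged, optionally filled by
linear interpolation when shorter than `max_gap`, and excluded from metrics
otherwise. Pose reconstruction from markers uses the centroid of visible
markers and a proper-rotation Kabsch fit of the marker model (a 100 × 60 mm
rectangle standing in for the real, unpublished marker geometry). CSV
interchange is bit-exact: values are written with `%.17g` and parsed with a
round-trip-exact parser, so file-based and in-memory runs produce identical
statistics.

## Problem sizes

Default analyses use 30 subjects × 2 trials (≈ 110 000 pooled 30 Hz frames,
90/180/90 squat/side-step/step-up repetitions). Calibration checks that need
large samples (noise limits, percentile limits, Lilliefors type-I error) use
10⁵–10⁶ draws or ≥ 10⁵ pooled frames from long free-play recordings; parameter
-recovery checks (lag, frame, amplitudes) use 100 seeds per condition.

## Known limitations

ICC values in the default synthetic study (~0.4–0.8) are lower than those
reported for the real instrument (0.96–0.998), because the synthetic cohort's
between-repetition amplitude spread (height scaling + 10% jitter) is narrower
than that of real humans relative to the injected tracking error; the ICC
machinery itself is exact (oracle-tested). Step-up amplitudes carry the
largest relative error — the smallest true amplitude over the longest
interval — which the default report reproduces. The free-rotation Procrustes
path reports its alignment rounded to the nearest signed permutation and is
intended for diagnostics, not as the default registration.
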