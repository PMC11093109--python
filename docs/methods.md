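# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `curvesprint`.

## Coordinate conventions and data model

The global frame is right-handed, z up, origin at the centre of the
force-plate pair; plate axes coincide with the global horizontal axes.
On the straightaway the running direction makes a fixed 14° angle with
the plate tangential axis (a facility constraint the pipeline corrects
for); on curves the lane tangent at the plates is aligned with the plate
axes and the curve centre sits on the ±y axis.  All stored quantities
are SI (N, m, s, kg); body-weight normalisation (BW = *m g*) happens
only inside computations.  The straight condition is encoded as an
infinite radius so model code can take r → ∞ limits naturally.

## Processing pipeline

**Filtering.**  Force and marker series are filtered with the same
4th-order zero-lag low-pass Butterworth filter, 50 Hz cutoff
(`scipy.signal.sosfiltfilt`; the two-pass magnitude response is the
squared one-pass response, phase shift zero).  A 10 Hz component changes
by well under 1 % per (double-pass) application.

**Stance detection.**  Stances are maximal intervals of vertical force
above 5 N, with the bounding threshold crossings linearly interpolated
between samples and a 50 ms debounce (sprint stances last ≥ ~80 ms;
noise chatters at 5 N).  Timing runs on the *raw* 1000 Hz force: the
zero-lag filter smears the pulse onset over a few milliseconds, which at
a 5 N threshold would systematically widen contact times by ~2 samples
per edge; the raw edges are sharp.  Stance averages are then taken from
the filtered series over the detected window, with end points
interpolated so the integral spans the exact stance duration.

**Off-plate gait events.**  The underlying rule — detect events from the
average foot-marker position when the athlete is not on a plate — is
operationalised as calibrated height crossings.  Per subject, the heel
height at force-defined heel-strike and the metatarsal height at
force-defined toe-off are averaged across every on-plate stance.  For
each leg, swing phases are located as regions where the marker clears
the calibrated level by ≥ 2 cm (beyond noise reach); the event time is
the crossing of the calibrated level at the region edge, estimated by a
line fit through the steep 4–50 mm band of the trajectory and
extrapolated to the level.  The fit is necessary because near the ground
the height flattens to within sensor noise of the level, making
single-sample crossing estimates jitter by whole frames; with it,
marker-based events agree with force-based events to ≤ 5 ms (one marker
frame) at default noise.

**Force rotation.**  For curve stances, horizontal plate forces are
projected onto a frame rotated by the angle subtended at the curve
centre between the global origin and the 3rd metatarsal head marker at
the time of peak vertical force; the centripetal axis points toward the
centre for both directions, so clockwise and counterclockwise trials
pool without sign flips.  Plate-sized offsets at the study radii keep
this angle below 3°.  Straight trials use the fixed 14° plate-path
angle, and their "centripetal" axis is simply the mediolateral axis
(reported, excluded from curve statistics).  Rotation preserves
per-sample horizontal magnitude to machine precision.

**Summary metrics.**  Stance-average cGRF and vGRF are time averages
over the stance normalised by BW; the stance-average resultant is
√(cGRF² + vGRF²) computed per trial from the two averages (deliberately
ignoring the tangential component, and *not* averaging instantaneous
resultants — group means of resultants therefore need not equal the
vector sum of group-mean components).  Impulses are trapezoidal
integrals of the tangential force (positive part = propulsive, negative
magnitude = braking).  Step variables follow the standard definitions
(t_step = t_c + subsequent t_a; t_swing = t_a + subsequent t_step; step
frequency = 1/t_step), attached to the event opening each interval;
broken chains yield missing values rather than fabricated ones.
Contact length is the transverse-plane polyline length of the 6-marker
pelvis centroid (the centre-of-mass proxy) between heel-strike and
toe-off, with sub-frame end-point interpolation.  Maximum velocity is
the mean horizontal centroid speed (central differences of filtered
positions) across the ~5 m capture volume; on the straightaway, where
athletes peak beyond the volume, it is the maximum of a 0.32 s moving
average of the radar trace (15 samples at 47 Hz, nearest-integer
rounding of 0.32 × 47 = 15.04).

## Maximum-velocity models

All three models share the effective-gravity idea: holding speed *v* on
a flat curve of radius *r* requires centripetal acceleration *v²/r*, so
the stance limb effectively supports g′(v) = √(g² + (v²/r)²).

* **Constant-resultant-force model** (inputs *V*, *r*, *g* only):
  implemented in the closed form v = V·[1 − (2/5)·(V²/(g r))^{5/2}].
  At the study's group-mean V = 9.12 m/s it predicts 6.8 % slowing at
  r = 17.2 m and 1.0 % at r = 36.5 m — the least slowing of the three
  models at both radii, consistent with its role as an upper bound on
  curve performance.  Its domain requires V²/(g r) < (5/2)^{2/5}
  (roughly r > V²/1.44 g); study radii sit comfortably inside.
* **Aerial-time-compression model** (inputs *V*, t_a, L_c, t_step):
  contact length and step frequency are radius-independent, while the
  ballistic aerial time scales as g/g′; the speed solves
  v·(t_step − t_a·g/g′(v)) = V·(t_step − t_a).  The right-hand side
  anchors v(r→∞) = V even when the supplied kinematics are slightly
  inconsistent with V.
* **Constant-force / constant-swing-time model** (inputs *V*, t_swing,
  L_c): the stance-average resultant (in BW) implied by the
  straight-path condition, f = (V·t_swing/L_c + 1)/2, is held fixed and
  the duty factor absorbs the effective-weight increase; the speed
  solves v·(2f − 1)·g′/g = V·(2f − g′/g).

Implicit forms are solved by deterministic bisection on (0, V] to
|Δv| < 1e−9 m/s; tests cross-check every model against an independent
`brentq` solve of the same balance.  Group predictions are computed per
subject from individual straight-path v_max (and, for the kinematic
models, straight-trial kinematic averages — the natural reading, flagged
as an assumption since at maximal effort kinematics could equally be
taken from curve trials) and then averaged.

## Synthetic-data generator

The generator emulates the experimental design the pipeline targets:
9 subjects × {straightaway, 17.2 m, 36.5 m} × {CCW, CW}, two trials per
condition so each leg lands on a plate at least once, ~10 steps per
trial with the middle stance on the plate pair.

* **Speeds.**  Straight-path v_max is drawn per subject from
  N(9.12, 0.60²) m/s; curve speeds scale each subject by the group
  ratios (8.21/9.12 at 17.2 m, 8.75/9.12 at 36.5 m, i.e. 10.0 % and
  4.1 % mean slowing) with a ±0.07 m/s direction offset (CCW faster by
  0.14 m/s).  Curve trials run at constant speed on a circular arc, so
  stride-average centripetal force is exactly m v²/r.
* **Forces.**  Vertical and centripetal stance pulses are half-sines
  (the standard spring-mass approximation; peak = π/2 × stance average,
  closed-form averages for tests).  Stance averages are set by impulse
  shares: per stride, vertical impulse equals m g t_stride and
  centripetal impulse m(v²/r)t_stride exactly, split between inside and
  outside legs at configured shares.  Defaults — duty factor 0.556 /
  0.52 / 0.50 and vertical shares 0.472 / 0.487 / 0.5 (17.2 m / 36.5 m /
  straight) — place stance-average vGRF at 1.70/1.90 BW (17.2 m) and
  1.87/1.97 BW (36.5 m) for inside/outside legs, the leg-specific
  pattern of interest; contact time is not independently reported for
  these conditions, so duty factors are tunable emulation constants, not
  ground truth.  The tangential component is an odd one-cycle sine
  (braking then propulsion) with zero net impulse on curves and a
  +0.04 N·s net per step on the straightaway (athletes still accelerate
  slightly at the plates there).
* **Markers.**  Six pelvis markers ride a rigid cluster whose centroid
  is exactly the generated centre-of-mass path (offsets sum to zero),
  with a 4 cm vertical bounce at step frequency.  Foot markers rest at
  the touchdown point during stance and follow a smooth zero-end-slope
  interpolant (12 cm apex) between footfalls, giving the height
  signatures the event detector relies on.
* **Straightaway quirks.**  The lane is rotated 14° from the plate axes.
  Speed follows a logistic profile whose capture-volume mean sits a
  configurable 0.44 m/s below the plateau (solved per trial by
  bisection on the logistic midpoint), so the radar maximum exceeds the
  capture-volume measurement and v_max is reached a few metres past the
  volume.
* **Noise.**  Additive Gaussian, independent per channel: 2 N (forces),
  1 mm (markers), 0.05 m/s (radar).  Small enough not to mask recovery,
  non-zero to exercise the filters; everything is a pure function of the
  seed.

What the generator does **not** emulate: waveform shape variety (real
sprint vGRF has an impact transient), within-trial speed fluctuation on
curves, marker soft-tissue artefact and dropout, step-width and
foot-angle variability, curve banking, and fatigue across trials.
Passing recovery tests therefore demonstrates the pipeline's
correctness on idealised but physically consistent signals, not
robustness to every artefact of real motion-capture data.

## Statistics

Mixed models are fit by REML (`statsmodels` MixedLM) with categorical
fixed effects and a per-athlete random intercept — the random structure
named by the study design.  Models start with interaction terms;
following the coefficient-significance reading of pruning, the
interaction term with the largest non-significant (p ≥ 0.05) Wald p is
removed and the model refit, iterating; main effects are always
retained (whether main effects were also pruned is ambiguous in the
source description; interactions-only is the conservative choice and is
logged).  Singular fits fall back to an ordinary least-squares model
with athlete fixed blocks, flagged in the result.  Post hoc simple
effects are estimated-marginal-mean contrasts: cell design rows average
the remaining factors over their observed levels with equal weight, the
contrast variance comes from the fixed-effect covariance, and the
Bonferroni-corrected per-comparison alpha (0.05 / family size; 0.0125
for the standard four-contrast leg-by-radius family) is reported beside
each p-value.  Model-vs-measurement agreement uses paired t-tests on
per-subject percent slowing; zero-variance difference vectors are
reported as exact ties rather than errors.

## Numerical choices and test scales

* Threshold crossings, integral end points and contact-length end points
  are linearly interpolated between samples; trapezoidal integration on
  the native grids, no resampling.
* Bisection tolerances: 1e−9 m/s (models), 50 iterations (logistic
  midpoint).  Ties in pruning break lexicographically.
* Degenerate inputs raise with named fields: zero-length radar series,
  cutoffs at/above Nyquist, stances truncated by the record, coincident
  rotation geometry, model inputs outside the physical domain.
* Test problem sizes: most tests run on 2-subject sessions; the
  full-recovery and statistical-coverage checks use the study scale
  (9 subjects × 5 conditions × 2 trials; 50 seeded replicates for CI
  coverage), which keeps the whole suite under a minute.

## Limitations

* The constant-resultant-force model is implemented as a closed form
  chosen to match the published model-prediction values at the study
  radii; away from ~15–50 m radii its extrapolation is less certain than
  the two mechanistic implicit models.
* Off-plate event detection assumes reasonably clean foot-marker height
  trajectories; heavy marker dropout inside a stance yields missing
  values with QC flags rather than estimates.
* The pipeline computes straight-trial kinematics and GRFs but excludes
  them from curve statistics (athletes are not at v_max over the plates
  on the straightaway); straight-path v_max comes from the radar.
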