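# curvesprint

Leg-specific ground reaction forces, step kinematics and maximum-velocity
models for sprinting on flat curves.

## The problem

Sprinters are slower on curves than on straight paths.  Turning at speed
*v* on a flat curve of radius *r* requires a centripetal ground reaction
force (cGRF) of *m v²/r*, produced during stance alongside the vertical
force that supports body weight — and the leg on the inside of the curve
behaves differently from the leg on the outside.  Track-and-field radii
range from 17.2 m (innermost lane of an indoor 200 m track) to 45 m, so
the effect is competitively meaningful: a few percent of maximum velocity
over half a race.

`curvesprint` is a tested pipeline for this analysis problem:

* **Synthesis** (`synth`): generates maximum-effort sprint sessions —
  force-plate series (1000 Hz), labelled pelvis/foot marker series
  (200 Hz) and radar speed traces (47 Hz) — on a straightaway and on
  17.2 m / 36.5 m curves in both directions, with exact stride-level
  impulse balance (vertical impulse = *m g t*<sub>stride</sub>,
  centripetal impulse = *m v²/r · t*<sub>stride</sub>), configurable
  inside/outside-leg asymmetries, and known ground truth for every
  quantity the pipeline later estimates.
* **Processing** (`preprocess`, `grf`, `kinematics`, `pipeline`):
  zero-lag 4th-order 50 Hz Butterworth filtering; stance detection at a
  5 N vertical-force threshold; marker-based gait events for steps taken
  off the plates (calibrated per subject from on-plate steps); rotation
  of plate-frame horizontal forces into centripetal/tangential axes from
  the curve geometry; stance-average cGRF/vGRF and their vector-sum
  resultant in body weights; propulsive/braking impulses; contact time
  t_c, aerial time t_a, step time t_step, swing time t_swing, step
  frequency, contact length L_c; capture-volume and radar maximum
  velocity.
* **Models** (`models`): three published predictions of curve-running
  maximum velocity from the straight-path maximum *V*:
  a constant-resultant-force model
  (v = V·[1 − (2/5)(V²/gr)^5/2], inputs *V*, *r*, *g* only), an
  aerial-time-compression model (effective gravity
  g′ = √(g² + (v²/r)²) shortens ballistic aerial time at constant L_c
  and step frequency), and a constant-force/constant-swing-time model
  (duty factor absorbs the effective-weight increase).  All satisfy
  v → V as r → ∞ and are monotone in r.
* **Statistics** (`stats`): linear mixed-effects models (restricted
  maximum likelihood; condition, leg role and direction as categorical
  fixed effects, athlete as a random intercept), Wald-p pruning of
  non-significant interactions, estimated-marginal-mean post hocs under
  a Bonferroni-corrected alpha (0.05/4 = 0.0125 for the standard
  leg-by-radius family), and paired t-tests of model predictions
  against measured slowing.

## Worked example

```sh
python examples/simulate_and_process.py
```

generates a two-subject session, processes it, and prints (abridged):

```
on-plate stance-average recovery (BW):
  S01_r17.2_CCW_left       inside  vGRF  1.70 (true  1.70)  cGRF  0.78 (true  0.78)
  S01_r17.2_CCW_right      outside vGRF  1.90 (true  1.90)  cGRF  0.74 (true  0.74)
  S01_r36.5_CCW_left       inside  vGRF  1.87 (true  1.87)  cGRF  0.48 (true  0.48)
  S01_r36.5_CCW_right      outside vGRF  1.97 (true  1.97)  cGRF  0.38 (true  0.38)

per-subject percent slowing (directions pooled):
subject_id  radius  slowing_pct
       S01    17.2        10.13
       S01    36.5         4.23
```

The recovered stance averages match the generator's ground truth to two
decimals at realistic sensor noise, the inside leg carries less vertical
force than the outside leg, and maximum velocity drops ~10 % on the
17.2 m curve versus ~4 % on the 36.5 m curve.  `examples/model_predictions.py`
prints the model comparison (6.8 / 7.3 / 9.6 % predicted slowing at
17.2 m for the three models) and `examples/leg_asymmetry_stats.py` the
mixed-model and post-hoc analysis of leg asymmetry.

A `curvesprint` CLI chains the same stages from a shell:
`curvesprint simulate | process | models | stats`.

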