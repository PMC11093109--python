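"""Evaluate the three curve-running maximum-velocity models.

Each model predicts how much a sprinter's straight-path maximum velocity
(V = 9.12 m/s here, the study group mean) must drop on a flat curve.
The force-only model needs just V, r and g; the two kinematic models
additionally use aerial time, contact length, step time and swing time.
"""

import pandas as pd

import curvesprint as cs

V = 9.12  # straight-path v_max, m/s
KIN = dict(t_a=0.115, L_c=1.00, t_step=0.23, t_swing=0.345)  # sprint-typical

rows = []
for r in (17.2, 36.5):
    rows.append(
        {
            "radius_m": r,
            "greene_eq2": cs.percent_slowing(V, cs.greene_vmax(V, r)),
            "mcmahon_eq1": cs.percent_slowing(
                V, cs.mcmahon_vmax(V, KIN["t_a"], KIN["L_c"], KIN["t_step"], r)
            ),
            "usherwood_eq3": cs.percent_slowing(
                V, cs.usherwood_vmax(V, KIN["t_swing"], KIN["L_c"], r)
            ),
        }
    )
print("predicted percent slowing vs the straight path:")
print(pd.DataFrame(rows).round(1).to_string(index=False))

print("\nradius sweep (percent of straight-path v_max retained):")
sweep = cs.radius_sweep(V, 15, 120, 8, **KIN)
for col in cs.MODEL_NAMES:
    sweep[col] = 100 * sweep[col] / V
print(sweep.round(1).to_string(index=False))
print("\nThe constant-force model is the most optimistic at every radius;")
print("all three converge to the straight-path maximum as r grows.")
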