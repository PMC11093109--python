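"""Published maximum-velocity models for flat curve running.

Three models predict the maximum velocity v on a flat curve of radius r
from the straight-path maximum V.  All share the effective-gravity idea:
turning at speed v requires a centripetal acceleration v^2/r, so the
stance leg must support an effective gravity

    g'(v) = sqrt(g^2 + (v^2 / r)^2)

but they close the problem with different constancy assumptions.

``greene_vmax``
    Constant-resultant-force model, a function of V, r and g only, in the
    closed form v = V * (1 - (2/5) * (V^2/(g r))**2.5).
``mcmahon_vmax``
    Aerial-time-compression model: contact length L_c and step frequency
    are radius independent, while ballistic aerial time shrinks in
    proportion to g/g', which lengthens contact and slows the runner.
``usherwood_vmax``
    Constant-force, constant-swing-time model: the leg's stance-average
    resultant force (in body weights, implied by the straight-path
    condition) and t_swing are fixed; the duty factor absorbs the
    effective-weight increase.

Implicit forms are solved by deterministic bisection on (0, V] to
|dv| < 1e-9 m/s.  All models satisfy v -> V as r -> inf and are
nondecreasing in r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MCMAHON = "mcmahon_eq1"
GREENE = "greene_eq2"
USHERWOOD = "usherwood_eq3"
MODEL_NAMES = (MCMAHON, GREENE, USHERWOOD)

_TOL = 1e-9


class ModelDomainError(ValueError):
    """Inputs outside a model's physical domain (no root in (0, V])."""


@dataclass
class ModelPrediction:
    model: str
    subject_id: str
    radius: float
    v_pred: float
    slowing_pred: float  # percent


def _effective_gravity_ratio(v: float, r: float, g: float) -> float:
    return math.hypot(1.0, v * v / (g * r))


def _bisect(f, lo: float, hi: float) -> float:
    flo, fhi = f(lo), f(hi)
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    if flo * fhi > 0:
        raise ModelDomainError("no root bracketed in (0, V]")
    while hi - lo > _TOL:
        mid = 0.5 * (lo + hi)
        if f(mid) * flo <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def greene_vmax(V: float, r: float, g: float = 9.81) -> float:
    """Constant-resultant-force prediction of curve v_max (m/s).

    Closed form in the single dimensionless group k = V^2/(g r):
    v = V * (1 - 0.4 * k**2.5).  Inputs must satisfy k < (5/2)**(2/5)
    (about r > V^2/(1.44 g)) for a physical, positive speed.
    """
    if V <= 0 or r <= 0 or g <= 0:
        raise ModelDomainError("V, r and g must be positive")
    k = V * V / (g * r)
    v = V * (1.0 - 0.4 * k**2.5)
    if v <= 0:
        raise ModelDomainError(f"radius {r} m too small for the model domain at V={V}")
    return v


def mcmahon_vmax(
    V: float, t_a: float, L_c: float, t_step: float, r: float, g: float = 9.81
) -> float:
    """Aerial-time-compression prediction of curve v_max (m/s).

    Solves v * (t_step - t_a * g / g'(v)) = V * (t_step - t_a) by
    bisection; the right-hand side anchors the straight-path condition
    v(r -> inf) = V regardless of small inconsistencies between V and the
    measured kinematics.
    """
    for name, val in (("V", V), ("t_a", t_a), ("L_c", L_c), ("t_step", t_step), ("r", r)):
        if val <= 0:
            raise ModelDomainError(f"{name} must be positive, got {val}")
    if t_a >= t_step:
        raise ModelDomainError("t_a must be smaller than t_step")
    if L_c / (t_step - t_a) > 15.0:
        raise ModelDomainError("L_c / t_c implies a non-physical contact speed")
    rhs = V * (t_step - t_a)

    def f(v):
        return v * (t_step - t_a / _effective_gravity_ratio(v, r, g)) - rhs

    return _bisect(f, _TOL, V)


def usherwood_vmax(
    V: float, t_swing: float, L_c: float, r: float, g: float = 9.81
) -> float:
    """Constant-force, constant-swing-time prediction of curve v_max (m/s).

    The straight-path condition V = L_c (2f - 1) / t_swing fixes the
    stance-average resultant force f (in body weights); on the curve the
    duty factor grows with the effective weight and the speed solves
    v (2f - 1) g'(v)/g = V (2f - g'(v)/g).
    """
    for name, val in (("V", V), ("t_swing", t_swing), ("L_c", L_c), ("r", r)):
        if val <= 0:
            raise ModelDomainError(f"{name} must be positive, got {val}")
    f_bw = 0.5 * (V * t_swing / L_c + 1.0)

    def resid(v):
        ratio = _effective_gravity_ratio(v, r, g)
        return v * (2 * f_bw - 1.0) * ratio - V * (2 * f_bw - ratio)

    # Domain check at the straight-path speed: force must cover the
    # effective weight somewhere in the bracket.
    if 2 * f_bw <= _effective_gravity_ratio(_TOL, r, g):
        raise ModelDomainError("required effective weight exceeds the leg force f")
    return _bisect(resid, _TOL, V)


def predict_session(
    measurements: pd.DataFrame,
    radii: list[float],
    g: float = 9.81,
) -> pd.DataFrame:
    """Per-subject model predictions for each model x radius.

    ``measurements`` needs one row per subject with columns ``subject_id``
    and ``v_straight``; kinematic inputs ``t_a``, ``L_c``, ``t_step``,
    ``t_swing`` are used when present and finite.  The force-only model is
    always computed; the kinematic models are flagged missing (NaN) when
    their inputs are absent.
    """
    rows = []
    for rec in measurements.to_dict("records"):
        V = float(rec["v_straight"])
        for r in radii:
            preds = {GREENE: greene_vmax(V, r, g)}
            has_kin = all(
                np.isfinite(rec.get(kk, np.nan)) for kk in ("t_a", "L_c", "t_step")
            )
            preds[MCMAHON] = (
                mcmahon_vmax(V, rec["t_a"], rec["L_c"], rec["t_step"], r, g)
                if has_kin
                else np.nan
            )
            has_swing = all(
                np.isfinite(rec.get(kk, np.nan)) for kk in ("t_swing", "L_c")
            )
            preds[USHERWOOD] = (
                usherwood_vmax(V, rec["t_swing"], rec["L_c"], r, g)
                if has_swing
                else np.nan
            )
            for model in MODEL_NAMES:
                v = preds[model]
                rows.append(
                    {
                        "subject_id": rec["subject_id"],
                        "model": model,
                        "radius": r,
                        "v_pred": v,
                        "slowing_pred": 100.0 * (V - v) / V,
                    }
                )
    return pd.DataFrame(rows)


def group_summary(predictions: pd.DataFrame) -> pd.DataFrame:
    """Mean and s.d. of per-subject percent slowing for each model x radius."""
    return (
        predictions.groupby(["model", "radius"])["slowing_pred"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "slowing_mean", "std": "slowing_sd", "count": "n"})
    )


def radius_sweep(
    V: float,
    r_min: float,
    r_max: float,
    n: int,
    t_a: float | None = None,
    L_c: float | None = None,
    t_step: float | None = None,
    t_swing: float | None = None,
    g: float = 9.81,
) -> pd.DataFrame:
    """Model curves over a log-spaced radius grid (the model-comparison sweep)."""
    radii = np.geomspace(r_min, r_max, n)
    rows = []
    for r in radii:
        row = {"radius": float(r), GREENE: greene_vmax(V, r, g)}
        if None not in (t_a, L_c, t_step):
            row[MCMAHON] = mcmahon_vmax(V, t_a, L_c, t_step, r, g)
        if None not in (t_swing, L_c):
            row[USHERWOOD] = usherwood_vmax(V, t_swing, L_c, r, g)
        rows.append(row)
    return pd.DataFrame(rows)
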