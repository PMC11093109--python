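"""Synthetic maximum-effort sprint sessions with known ground truth.

The generator emulates the experimental setup the processing pipeline is
built for: maximum-effort sprints along a 40 m straightaway and along flat
curves of 17.2 m and 36.5 m radius in both directions, with two force
plates and a ~5 m motion-capture volume halfway along the lane, and a
radar gun covering the straightaway (where sprinters only peak a few
metres beyond the capture volume).

Physics built into every curve trial
------------------------------------
* The pelvis centroid travels a circular arc at constant speed v, so the
  stride-average centripetal force is exactly m v^2 / r.
* Legs alternate; the per-stride vertical impulse equals m g t_stride and
  the centripetal impulse m (v^2/r) t_stride, split between the inside
  and outside legs at configurable shares.
* Ground reaction force pulses are half-sines (the standard spring-mass
  approximation), whose peak is pi/2 times the stance average, plus an
  odd one-cycle sine tangential component (braking then propulsion) whose
  net impulse is zero on curves and configurable on the straight.
* Facility quirks: the straightaway runs 14 deg oblique to the plate
  axes, and straight-trial speed still rises through the capture volume,
  peaking a few metres past it, with the radar plateau sitting above the
  capture-volume average by a configurable offset.

Additive Gaussian sensor noise (forces, markers, radar) is independent
per channel.  Everything is a pure function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import INSIDE, LEFT, OUTSIDE, RIGHT
from .trial import (
    CCW,
    CURVE,
    CW,
    INF_RADIUS,
    NA,
    STRAIGHT,
    ForceSeries,
    MarkerSeries,
    RadarSeries,
    Trial,
    TrialMeta,
)

#: Capture-volume bounds (xmin, xmax, ymin, ymax) in the global frame, m.
CAPTURE_BOUNDS = (-2.5, 2.5, -1.5, 1.5)

#: Force-plate pair footprint (two 1.2 x 0.6 m plates end to end), m.
PLATE_X, PLATE_Y = 1.2, 0.3

_PELVIS_OFFSETS = {
    # body frame: (forward, left, up); offsets sum to zero so the marker
    # centroid coincides with the generated centre-of-mass path.
    "LIC": (0.00, 0.14, 0.03),
    "RIC": (0.00, -0.14, 0.03),
    "LASIS": (0.09, 0.11, -0.02),
    "RASIS": (0.09, -0.11, -0.02),
    "LPSIS": (-0.09, 0.06, -0.01),
    "RPSIS": (-0.09, -0.06, -0.01),
}


@dataclass
class ConditionSpec:
    """Gait parameters for one lane condition."""

    name: str
    radius: float  # m; INF_RADIUS for the straight
    speed_mean: float  # group-mean true speed, m/s
    duty_factor: float  # t_c / t_step
    v_share_inside: float  # inside-leg share of stride vertical impulse
    c_share_inside: float  # inside-leg share of stride centripetal impulse


def default_conditions() -> list[ConditionSpec]:
    """Study conditions: group speeds 9.12 / 8.21 / 8.75 m/s; duty factors
    and impulse shares chosen so stance-average vertical forces land at the
    leg-specific levels the study design targets (inside leg unloaded)."""
    return [
        ConditionSpec(STRAIGHT, INF_RADIUS, 9.12, 0.50, 0.5, 0.5),
        ConditionSpec("r17.2", 17.2, 8.21, 0.556, 0.472, 0.511),
        ConditionSpec("r36.5", 36.5, 8.75, 0.520, 0.487, 0.558),
    ]


@dataclass
class SynthConfig:
    n_subjects: int = 9
    straight_vmax_mean: float = 9.12  # m/s
    straight_vmax_sd: float = 0.60  # between-subject, m/s
    direction_effect: float = 0.14  # CCW minus CW true speed, m/s
    step_frequency: float = 4.35  # Hz
    conditions: list[ConditionSpec] = field(default_factory=default_conditions)
    body_mass_mean: float = 74.6  # kg
    body_mass_sd: float = 9.5  # kg
    tangential_amplitude_bw: float = 0.35  # brake/propel half-wave, BW
    net_impulse_straight: float = 0.04  # N*s per step, straight trials
    radar_offset: float = 0.44  # radar v_max above capture-volume speed, m/s
    noise_force: float = 2.0  # N
    noise_marker: float = 0.001  # m
    noise_radar: float = 0.05  # m/s
    n_steps: int = 10
    swing_height: float = 0.12  # m
    step_width: float = 0.12  # m
    gravity: float = 9.81
    force_rate: float = 1000.0
    marker_rate: float = 200.0
    radar_rate: float = 47.0
    seed: int = 0

    def validate(self) -> "SynthConfig":
        problems = []
        for c in self.conditions:
            if not 0 < c.duty_factor < 1:
                problems.append(f"{c.name}: duty factor must lie in (0, 1)")
            for share in (c.v_share_inside, c.c_share_inside):
                if not 0 < share < 1:
                    problems.append(f"{c.name}: impulse shares must lie in (0, 1)")
            if c.speed_mean <= 0:
                problems.append(f"{c.name}: speed must be positive")
        if self.straight_vmax_mean <= 0:
            problems.append("straight_vmax_mean must be positive")
        if problems:
            raise ValueError("; ".join(problems))
        return self


@dataclass
class GroundTruth:
    """Recovery oracle: per-trial speeds and per-stance true metrics."""

    trials: pd.DataFrame
    stances: pd.DataFrame


def stance_waveform(
    stance_avg_bw: float, t_c: float, rate: float, body_weight: float
) -> np.ndarray:
    """Half-sine force pulse with a prescribed stance average.

    The time average of sin over a half period is 2/pi, so the peak is
    (pi/2) * stance_avg_bw * body_weight and the pulse impulse is
    stance_avg_bw * body_weight * t_c.
    """
    if stance_avg_bw <= 0 or t_c <= 0:
        raise ValueError("stance average and contact time must be positive")
    n = int(round(t_c * rate))
    if n < 3:
        raise ValueError(f"contact time {t_c} s spans under 3 samples at {rate} Hz")
    t = np.arange(n + 1) / rate
    pulse = np.sin(math.pi * np.minimum(t, t_c) / t_c)
    return (math.pi / 2) * stance_avg_bw * body_weight * np.clip(pulse, 0.0, None)


class _Path:
    """Arc-length parametrised lane geometry through the global origin."""

    def __init__(self, radius: float, direction: str, plate_path_angle: float):
        self.radius = radius
        self.direction = direction
        self.straight = math.isinf(radius)
        if self.straight:
            a = math.radians(plate_path_angle)
            self.u = np.array([math.cos(a), math.sin(a)])
            self.center = None
        else:
            self.center = np.array([0.0, radius if direction == CCW else -radius])

    def pos(self, s):
        """Global horizontal position at arc length s (s=0 at the origin)."""
        s = np.asarray(s, dtype=float)
        if self.straight:
            return np.stack([s * self.u[0], s * self.u[1]], axis=-1)
        th = s / self.radius
        if self.direction == CCW:
            xy = np.stack([np.sin(th), -np.cos(th)], axis=-1)
        else:
            xy = np.stack([np.sin(th), np.cos(th)], axis=-1)
        return self.center + self.radius * xy

    def tangent(self, s):
        s = np.asarray(s, dtype=float)
        if self.straight:
            return np.broadcast_to(self.u, s.shape + (2,)).copy()
        th = s / self.radius
        sign = 1.0 if self.direction == CCW else -1.0
        return np.stack([np.cos(th), sign * np.sin(th)], axis=-1)

    def left_normal(self, s):
        t = self.tangent(s)
        return np.stack([-t[..., 1], t[..., 0]], axis=-1)


def pelvis_trajectory(
    speed: float,
    radius: float,
    direction: str,
    duration: float,
    rate: float = 200.0,
    step_frequency: float = 4.35,
    bounce_amplitude: float = 0.04,
    height: float = 1.0,
    plate_path_angle: float = 14.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Constant-speed pelvis-centroid path (circular arc or straight line).

    Returns (time, xyz); the horizontal speed of the path equals ``speed``
    and the vertical coordinate oscillates at the step frequency.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    path = _Path(radius, direction, plate_path_angle)
    t = np.arange(int(round(duration * rate)) + 1) / rate
    s = speed * (t - t[-1] / 2)
    xy = path.pos(s)
    z = height - bounce_amplitude * np.cos(2 * math.pi * step_frequency * t)
    return t, np.column_stack([xy, z])


def _smoothstep(tau):
    """Monotone 0->1 blend with zero end slopes (no foot slide at contact)."""
    return tau - np.sin(2 * math.pi * tau) / (2 * math.pi)


def _foot_series(time, path, leg_events, lateral, swing_height):
    """Met/heel marker series for one leg from its stance event list."""
    n = len(time)
    s_foot = np.empty(n)
    z = np.zeros(n)
    first, last = leg_events[0], leg_events[-1]
    s_foot[:] = first["s"]
    s_foot[time > last["t_to"]] = last["s"]
    for ev in leg_events:
        s_foot[(time >= ev["t_hs"]) & (time <= ev["t_to"])] = ev["s"]
    for a, b in zip(leg_events, leg_events[1:]):
        mask = (time > a["t_to"]) & (time < b["t_hs"])
        tau = (time[mask] - a["t_to"]) / (b["t_hs"] - a["t_to"])
        s_foot[mask] = a["s"] + (b["s"] - a["s"]) * _smoothstep(tau)
        z[mask] = swing_height * np.sin(math.pi * tau)
    met_xy = path.pos(s_foot) + lateral * path.left_normal(s_foot)
    heel_xy = path.pos(s_foot - 0.15) + lateral * path.left_normal(s_foot - 0.15)
    met = np.column_stack([met_xy, z])
    heel = np.column_stack([heel_xy, z])
    return met, heel


def _straight_speed_profile(t, v_f, t_ref, tau, offset, in_volume_halfwidth):
    """Logistic speed trace whose capture-volume mean sits ``offset`` below
    the plateau v_f.  The logistic midpoint is solved by bisection."""

    def capture_gap(tm):
        v = v_f / (1.0 + np.exp(-(t - tm) / tau))
        dt = t[1] - t[0]
        s = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * dt)])
        s -= np.interp(t_ref, t, s)
        mask = np.abs(s) <= in_volume_halfwidth
        return v_f - v[mask].mean(), v, s

    lo, hi = t_ref - 3.0, t_ref + 0.5
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        gap, v, s = capture_gap(mid)
        if gap > offset:
            hi = mid
        else:
            lo = mid
    gap, v, s = capture_gap(0.5 * (lo + hi))
    return v, s


def _make_trial(
    cfg: SynthConfig,
    subject_id: str,
    body_mass: float,
    cond: ConditionSpec,
    direction: str,
    v_true: float,
    plate_leg: str,
    trial_id: str,
    rng: np.random.Generator,
):
    g = cfg.gravity
    bw = body_mass * g
    t_step = 1.0 / cfg.step_frequency
    t_c = cond.duty_factor * t_step
    straight = math.isinf(cond.radius)
    path = _Path(cond.radius, direction, plate_path_angle=14.0 if straight else 0.0)

    n_steps = cfg.n_steps
    i_mid = n_steps // 2
    pad = 0.30
    t_hs = pad + np.arange(n_steps) * t_step
    t_to = t_hs + t_c
    t_ref = t_hs[i_mid] + t_c / 2  # plate-stance mid time, COM at the origin
    duration = t_to[-1] + pad

    mt = np.arange(int(round(duration * cfg.marker_rate)) + 1) / cfg.marker_rate
    ft = np.arange(int(round(duration * cfg.force_rate)) + 1) / cfg.force_rate

    # --- centre-of-mass arc length along the lane -------------------------
    if straight:
        v_f = v_true  # radar-plateau v_max
        halfwidth = min(
            CAPTURE_BOUNDS[1] / abs(path.u[0]), CAPTURE_BOUNDS[3] / abs(path.u[1])
        )
        v_m, s_m = _straight_speed_profile(
            mt, v_f, t_ref, tau=0.25, offset=cfg.radar_offset, in_volume_halfwidth=halfwidth
        )
        s_of_t = lambda tt: np.interp(tt, mt, s_m)
        xy_speed = v_m
        in_vol = np.abs(s_m) <= halfwidth
        v_capture_true = float(v_m[in_vol].mean())
    else:
        s_of_t = lambda tt: v_true * (np.asarray(tt) - t_ref)
        s_m = s_of_t(mt)
        xy_speed = np.full_like(mt, v_true)
        v_capture_true = v_true

    # --- stance bookkeeping ----------------------------------------------
    legs = [
        plate_leg if (i - i_mid) % 2 == 0 else (RIGHT if plate_leg == LEFT else LEFT)
        for i in range(n_steps)
    ]
    inside_leg = (LEFT if direction == CCW else RIGHT) if not straight else None
    s_mid = s_of_t(t_hs + t_c / 2)  # foot under the COM at mid-stance
    lateral = {LEFT: cfg.step_width / 2, RIGHT: -cfg.step_width / 2}

    c_level = 0.0 if straight else v_true**2 / (g * cond.radius)  # BW
    stance_rows = []
    for i in range(n_steps):
        leg = legs[i]
        role = NA if straight else (INSIDE if leg == inside_leg else OUTSIDE)
        if straight:
            v_share, c_share = 0.5, 0.5
        else:
            v_share = cond.v_share_inside if role == INSIDE else 1 - cond.v_share_inside
            c_share = cond.c_share_inside if role == INSIDE else 1 - cond.c_share_inside
        a_v = 2 * v_share / cond.duty_factor  # stance-average vGRF, BW
        a_c = 2 * c_share * c_level / cond.duty_factor  # stance-average cGRF, BW
        foot_xy = path.pos(s_mid[i]) + lateral[leg] * path.left_normal(s_mid[i])
        on_plate = abs(foot_xy[0]) <= PLATE_X and abs(foot_xy[1]) <= PLATE_Y
        t_a = t_step - t_c
        L_c = float(s_of_t(t_to[i]) - s_of_t(t_hs[i]))
        stance_rows.append(
            {
                "trial_id": trial_id,
                "subject_id": subject_id,
                "condition": cond.name,
                "radius": cond.radius,
                "direction": direction,
                "stance_index": i,
                "leg": leg,
                "role": role,
                "t_hs": float(t_hs[i]),
                "t_to": float(t_to[i]),
                "on_plate": bool(on_plate),
                "cgrf_avg_bw": a_c,
                "vgrf_avg_bw": a_v,
                "rgrf_avg_bw": math.hypot(a_c, a_v),
                "t_c": t_c,
                "t_a": t_a,
                "t_step": t_step,
                "t_swing": t_a + t_step,
                "step_frequency": 1.0 / t_step,
                "L_c": L_c,
                "net_tangential_impulse": cfg.net_impulse_straight if straight else 0.0,
                "s_foot": float(s_mid[i]),
                "foot_x": float(foot_xy[0]),
                "foot_y": float(foot_xy[1]),
            }
        )

    # --- markers ----------------------------------------------------------
    com_xy = path.pos(s_m)
    z = 1.0 - 0.04 * np.cos(2 * math.pi * (mt - t_ref - t_c / 2) / t_step)
    tang = path.tangent(s_m)
    left = path.left_normal(s_m)
    up = np.array([0.0, 0.0, 1.0])
    positions = {}
    for lab, (fwd, lat, dz) in _PELVIS_OFFSETS.items():
        xy = com_xy + fwd * tang + lat * left
        positions[lab] = np.column_stack([xy, z + dz])
    for leg, met_lab, heel_lab in ((LEFT, "LMET", "LHEEL"), (RIGHT, "RMET", "RHEEL")):
        leg_events = [
            {"t_hs": r["t_hs"], "t_to": r["t_to"], "s": r["s_foot"]}
            for r in stance_rows
            if r["leg"] == leg
        ]
        met, heel = _foot_series(mt, path, leg_events, lateral[leg], cfg.swing_height)
        positions[met_lab] = met
        positions[heel_lab] = heel
    for lab in positions:
        positions[lab] = positions[lab] + rng.normal(0, cfg.noise_marker, positions[lab].shape)

    # --- forces (plate-measured stances only) ------------------------------
    fx = np.zeros_like(ft)
    fy = np.zeros_like(ft)
    fz = np.zeros_like(ft)
    for r in stance_rows:
        if not r["on_plate"]:
            continue
        i0 = int(round(r["t_hs"] * cfg.force_rate))
        pulse_v = stance_waveform(r["vgrf_avg_bw"], t_c, cfg.force_rate, bw)
        npulse = len(pulse_v)
        tau = np.arange(npulse) / cfg.force_rate / t_c
        tangential = -cfg.tangential_amplitude_bw * bw * np.sin(2 * math.pi * tau)
        tangential += r["net_tangential_impulse"] / t_c
        if straight:
            c_pulse = np.zeros(npulse)
        else:
            c_pulse = stance_waveform(r["cgrf_avg_bw"], t_c, cfg.force_rate, bw)
        foot = np.array([r["foot_x"], r["foot_y"]])
        if straight:
            t_hat = path.u
            c_hat = np.array([-t_hat[1], t_hat[0]])
        else:
            c_hat = path.center - foot
            c_hat = c_hat / np.hypot(*c_hat)
            t_hat = (
                np.array([c_hat[1], -c_hat[0]])
                if direction == CCW
                else np.array([-c_hat[1], c_hat[0]])
            )
        sl = slice(i0, i0 + npulse)
        fx[sl] += c_pulse * c_hat[0] + tangential * t_hat[0]
        fy[sl] += c_pulse * c_hat[1] + tangential * t_hat[1]
        fz[sl] += pulse_v
    fx += rng.normal(0, cfg.noise_force, fx.shape)
    fy += rng.normal(0, cfg.noise_force, fy.shape)
    fz += rng.normal(0, cfg.noise_force, fz.shape)

    # --- radar (straight trials only) --------------------------------------
    radar = None
    if straight:
        rt = np.arange(int(round((t_ref + 1.8) * cfg.radar_rate)) + 1) / cfg.radar_rate
        rv = v_f / (1.0 + np.exp(-(rt - _logistic_midpoint(mt, v_m, v_f)) / 0.25))
        rv = rv + rng.normal(0, cfg.noise_radar, rv.shape)
        radar = RadarSeries(time=rt, speed=np.clip(rv, 0, None))

    meta = TrialMeta(
        trial_id=trial_id,
        subject_id=subject_id,
        body_mass=body_mass,
        condition=STRAIGHT if straight else CURVE,
        radius=cond.radius,
        direction=direction,
        curve_center=None if straight else (float(path.center[0]), float(path.center[1])),
        plate_path_angle=14.0 if straight else 0.0,
        force_rate=cfg.force_rate,
        marker_rate=cfg.marker_rate,
        radar_rate=cfg.radar_rate,
        gravity=g,
    )
    trial = Trial(
        meta=meta,
        forces=ForceSeries(time=ft, fx=fx, fy=fy, fz=fz),
        markers=MarkerSeries(time=mt, positions=positions),
        radar=radar,
    ).validate()

    trial_row = {
        "trial_id": trial_id,
        "subject_id": subject_id,
        "condition": cond.name,
        "radius": cond.radius,
        "direction": direction,
        "v_true": v_true,
        "v_capture_true": v_capture_true,
        "vmax_true": v_true,
    }
    return trial, trial_row, stance_rows


def _logistic_midpoint(t, v, v_f):
    """Recover the logistic midpoint from a solved speed trace."""
    return float(np.interp(v_f / 2, v, t))


def generate_session(config: SynthConfig) -> tuple[list[Trial], GroundTruth]:
    """Generate one full session: subjects x conditions x directions x legs.

    Each subject runs every condition (straight plus each curve radius in
    both directions) with one trial per plate leg, so every condition has
    at least one stance of each leg on a force plate.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials: list[Trial] = []
    trial_rows = []
    stance_rows = []

    v_straights = config.straight_vmax_mean + config.straight_vmax_sd * rng.standard_normal(
        config.n_subjects
    )
    masses = np.clip(
        config.body_mass_mean + config.body_mass_sd * rng.standard_normal(config.n_subjects),
        45.0,
        None,
    )
    for si in range(config.n_subjects):
        subject_id = f"S{si + 1:02d}"
        V = float(v_straights[si])
        for cond in config.conditions:
            straight = math.isinf(cond.radius)
            directions = [NA] if straight else [CCW, CW]
            for direction in directions:
                ratio = cond.speed_mean / config.straight_vmax_mean
                v = V * ratio
                if not straight:
                    v += (0.5 if direction == CCW else -0.5) * config.direction_effect
                for plate_leg in (LEFT, RIGHT):
                    trial_id = f"{subject_id}_{cond.name}_{direction}_{plate_leg}"
                    trial, trow, srows = _make_trial(
                        config,
                        subject_id,
                        float(masses[si]),
                        cond,
                        direction,
                        v,
                        plate_leg,
                        trial_id,
                        rng,
                    )
                    trials.append(trial)
                    trial_rows.append(trow)
                    stance_rows.extend(srows)

    gt = GroundTruth(trials=pd.DataFrame(trial_rows), stances=pd.DataFrame(stance_rows))
    return trials, gt


def vmax_table(
    n_subjects: int = 9,
    n_trials: int = 3,
    direction_effect: float = 0.14,
    noise_sd: float = 0.15,
    radius_effects: dict[float, float] | None = None,
    interaction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Lightweight per-trial v_max table for exercising the statistics layer.

    Rows are athlete x curve radius x direction x trial with
    v = athlete intercept + radius effect + direction effect/2 * (+-1)
    [+ optional radius x direction interaction on the 17.2 m CCW cell]
    + Gaussian trial noise.  No signal synthesis — this is the study's
    v_max design matrix with known coefficients.
    """
    if radius_effects is None:
        radius_effects = {17.2: -0.91, 36.5: -0.37}
    rng = np.random.default_rng(seed)
    base = 9.12 + 0.60 * rng.standard_normal(n_subjects)
    rows = []
    for si in range(n_subjects):
        for radius, eff in radius_effects.items():
            for direction in (CCW, CW):
                shift = (0.5 if direction == CCW else -0.5) * direction_effect
                extra = interaction if (direction == CCW and radius == 17.2) else 0.0
                for k in range(n_trials):
                    rows.append(
                        {
                            "athlete": f"S{si + 1:02d}",
                            "radius": radius,
                            "direction": direction,
                            "vmax": base[si]
                            + eff
                            + shift
                            + extra
                            + noise_sd * rng.standard_normal(),
                        }
                    )
    return pd.DataFrame(rows)
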