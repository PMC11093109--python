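"""End-to-end trial processing: raw series in, per-stance results out.

``process_session`` mirrors the experimental workflow: filter every series
(4th-order zero-lag Butterworth, 50 Hz), detect on-plate stances from the
5 N vertical-force threshold, identify the stance leg from foot-marker
motion, calibrate per-subject stance marker heights, recover off-plate
steps from the markers, then attach step variables, contact lengths,
capture-volume / radar maximum velocities and stance-average GRF metrics.
The output is a tidy table with one row per stance event plus QC flags.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import grf, kinematics
from .preprocess import (
    LEFT,
    RIGHT,
    StanceCalibration,
    StanceEvent,
    assign_roles,
    build_stance_calibration,
    check_alternation,
    detect_offplate_events,
    detect_stance,
    lowpass_zero_lag,
)
from .synth import CAPTURE_BOUNDS
from .trial import CURVE, STRAIGHT, FILTER_CUTOFF_HZ, MarkerSeries, Trial


def condition_label(trial: Trial) -> str:
    if trial.meta.condition == STRAIGHT:
        return STRAIGHT
    return f"r{trial.meta.radius:g}"


def _filtered(trial: Trial) -> tuple[np.ndarray, MarkerSeries]:
    """Low-pass filtered vertical force and marker series."""
    fz = lowpass_zero_lag(trial.forces.fz, FILTER_CUTOFF_HZ, trial.meta.force_rate)
    positions = {
        lab: lowpass_zero_lag(xyz, FILTER_CUTOFF_HZ, trial.meta.marker_rate)
        for lab, xyz in trial.markers.positions.items()
    }
    return fz, MarkerSeries(time=trial.markers.time, positions=positions)


def _identify_leg(markers: MarkerSeries, event: StanceEvent) -> str:
    """The stance leg's metatarsal marker is stationary during contact."""
    sel = (markers.time >= event.t_heelstrike) & (markers.time <= event.t_toeoff)
    disp = {}
    for leg, lab in ((LEFT, "LMET"), (RIGHT, "RMET")):
        xy = markers.positions[lab][sel, :2]
        disp[leg] = float(np.linalg.norm(xy[-1] - xy[0])) if len(xy) > 1 else math.inf
    return min(disp, key=disp.get)


def onplate_events(trial: Trial) -> list[StanceEvent]:
    """Force-defined stances with the leg identified from the markers.

    Thresholding runs on the raw vertical force: the zero-lag low-pass
    filter smears the pulse onset over a few milliseconds, which at a 5 N
    threshold biases contact times (and hence stance averages); the raw
    1000 Hz edges are sharp and the debounce removes noise chatter.
    """
    _, fmarkers = _filtered(trial)
    events = detect_stance(trial.forces.time, trial.forces.fz)
    for ev in events:
        ev.leg = _identify_leg(fmarkers, ev)
    return events


def session_calibrations(trials: list[Trial]) -> dict[str, StanceCalibration]:
    """Per-subject stance marker-height calibrations from on-plate steps."""
    by_subject: dict[str, list] = {}
    for trial in trials:
        by_subject.setdefault(trial.meta.subject_id, []).append(
            (trial, onplate_events(trial))
        )
    return {sid: build_stance_calibration(pairs) for sid, pairs in by_subject.items()}


def _merge_events(
    force_events: list[StanceEvent], marker_events: list[StanceEvent]
) -> list[StanceEvent]:
    """Union of events, preferring force timing where intervals overlap."""
    merged = list(force_events)
    for mev in marker_events:
        overlaps = any(
            fev.leg == mev.leg
            and mev.t_heelstrike < fev.t_toeoff
            and mev.t_toeoff > fev.t_heelstrike
            for fev in force_events
        )
        if not overlaps:
            merged.append(mev)
    return sorted(merged, key=lambda e: e.t_heelstrike)


def process_trial(
    trial: Trial, calibration: StanceCalibration
) -> tuple[pd.DataFrame, list[str]]:
    """Process one validated trial into per-stance result rows."""
    meta = trial.meta
    fz_filt, fmarkers = _filtered(trial)
    # Event timing from the raw force edges (see onplate_events); averages
    # below still use the filtered series.
    force_events = detect_stance(trial.forces.time, trial.forces.fz)
    for ev in force_events:
        ev.leg = _identify_leg(fmarkers, ev)

    marker_events = []
    for leg in (LEFT, RIGHT):
        marker_events += detect_offplate_events(fmarkers, calibration, leg)
    events = _merge_events(force_events, marker_events)
    events = assign_roles(events, meta.condition, meta.direction)
    qc = check_alternation(events)

    centroid = fmarkers.pelvis_centroid()
    step_vars = kinematics.step_variables(events)

    try:
        v_capture = kinematics.vmax_capture(fmarkers.time, centroid[:, :2], CAPTURE_BOUNDS)
    except ValueError as exc:
        v_capture = np.nan
        qc.append(f"vmax_capture:{exc}")
    v_radar = np.nan
    if meta.condition == STRAIGHT:
        if trial.radar is None:
            raise ValueError(f"{meta.trial_id}: straight trial without a radar series")
        v_radar = kinematics.vmax_radar(trial.radar, meta.radar_rate)

    fx = lowpass_zero_lag(trial.forces.fx, FILTER_CUTOFF_HZ, meta.force_rate)
    fy = lowpass_zero_lag(trial.forces.fy, FILTER_CUTOFF_HZ, meta.force_rate)

    rows = []
    for ev, sv in zip(sorted(events, key=lambda e: e.t_heelstrike), step_vars):
        row = {
            "trial_id": meta.trial_id,
            "subject_id": meta.subject_id,
            "condition": condition_label(trial),
            "radius": meta.radius,
            "direction": meta.direction,
            "leg": ev.leg,
            "role": ev.role,
            "on_plate": ev.on_plate,
            "t_hs": ev.t_heelstrike,
            "t_to": ev.t_toeoff,
            "t_c": sv.t_c,
            "t_a": sv.t_a,
            "t_step": sv.t_step,
            "t_swing": sv.t_swing,
            "step_frequency": sv.step_frequency,
            "v_capture": v_capture,
            "v_radar": v_radar,
            "qc_alternation": bool(qc and any(f.startswith("non_alternating") for f in qc)),
        }
        try:
            row["L_c"] = kinematics.contact_length(fmarkers.time, centroid[:, :2], ev)
        except ValueError:
            row["L_c"] = np.nan

        if ev.on_plate:
            met_lab = "LMET" if ev.leg == LEFT else "RMET"
            sel = (trial.forces.time >= ev.t_heelstrike) & (
                trial.forces.time <= ev.t_toeoff
            )
            t_peak = trial.forces.time[sel][int(np.argmax(fz_filt[sel]))]
            met = fmarkers.positions[met_lab]
            foot_point = (
                float(np.interp(t_peak, fmarkers.time, met[:, 0])),
                float(np.interp(t_peak, fmarkers.time, met[:, 1])),
            )
            centripetal, tangential, angle = grf.decompose_forces(fx, fy, meta, foot_point)
            try:
                summary = grf.stance_averages(
                    trial.forces.time,
                    centripetal,
                    fz_filt,
                    tangential,
                    ev,
                    meta.body_mass,
                    meta.gravity,
                    angle,
                )
                row.update(
                    {
                        "cgrf_avg_bw": summary.cgrf_avg,
                        "vgrf_avg_bw": summary.vgrf_avg,
                        "rgrf_avg_bw": summary.rgrf_avg,
                        "rotation_angle_deg": summary.rotation_angle,
                        "propulsive_impulse": summary.propulsive_impulse,
                        "braking_impulse": summary.braking_impulse,
                        "t_peak_vgrf": summary.t_peak_vgrf,
                    }
                )
            except ValueError as exc:
                qc.append(f"stance_truncated:{exc}")
        rows.append(row)
    return pd.DataFrame(rows), qc


def process_session(trials: list[Trial]) -> pd.DataFrame:
    """Process every trial of a session; one row per detected stance."""
    calibrations = session_calibrations(trials)
    frames = []
    for trial in trials:
        df, _ = process_trial(trial, calibrations[trial.meta.subject_id])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def subject_vmax(results: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition x direction maximum velocity.

    Straight trials use the radar maximum (athletes peak beyond the
    capture volume); curve trials the capture-volume average.
    """
    per_trial = results.drop_duplicates("trial_id")[
        ["trial_id", "subject_id", "condition", "radius", "direction", "v_capture", "v_radar"]
    ].copy()
    per_trial["vmax"] = np.where(
        per_trial["condition"] == STRAIGHT, per_trial["v_radar"], per_trial["v_capture"]
    )
    return (
        per_trial.groupby(["subject_id", "condition", "radius", "direction"], dropna=False)[
            "vmax"
        ]
        .mean()
        .reset_index()
    )


def slowing_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-subject percent slowing per curve radius, directions pooled."""
    vm = subject_vmax(results)
    straight = vm[vm["condition"] == STRAIGHT].set_index("subject_id")["vmax"]
    curves = vm[vm["condition"] != STRAIGHT]
    pooled = (
        curves.groupby(["subject_id", "condition", "radius"])["vmax"].mean().reset_index()
    )
    pooled["v_straight"] = pooled["subject_id"].map(straight)
    pooled["slowing_pct"] = [
        kinematics.percent_slowing(vs, vc)
        for vs, vc in zip(pooled["v_straight"], pooled["vmax"])
    ]
    return pooled


def subject_measurements(results: pd.DataFrame) -> pd.DataFrame:
    """Per-subject model inputs: straight v_max and straight-trial kinematics."""
    vm = subject_vmax(results)
    straight_v = vm[vm["condition"] == STRAIGHT].set_index("subject_id")["vmax"]
    kin = (
        results[results["condition"] == STRAIGHT]
        .groupby("subject_id")[["t_a", "L_c", "t_step", "t_swing"]]
        .mean()
    )
    out = kin.copy()
    out["v_straight"] = straight_v
    return out.reset_index()
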