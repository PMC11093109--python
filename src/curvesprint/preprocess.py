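"""Signal conditioning and gait-event detection.

Force and marker series are low-pass filtered with the same 4th-order,
50 Hz zero-lag Butterworth filter (forward-backward application, so the
effective magnitude response is the squared single-pass response and the
phase shift is zero).  Stance phases on the plates are maximal intervals
of vertical force above a 5 N threshold.  Steps taken off the plates are
recovered from the foot markers: per subject, the heel and metatarsal
marker heights observed at force-defined heel-strike and toe-off are
averaged into a calibration, and off-plate events are height crossings
through those calibrated levels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .trial import CURVE, MarkerSeries, Trial

LEFT = "left"
RIGHT = "right"
INSIDE = "inside"
OUTSIDE = "outside"

#: Stance-phase detection threshold on vertical GRF, newtons.
STANCE_THRESHOLD_N = 5.0

#: Minimum stance duration; shorter supra-threshold intervals are noise
#: chatter (sprint stances last >= ~80 ms).
DEBOUNCE_S = 0.050

@dataclass
class StanceEvent:
    """One foot-ground contact."""

    leg: str  # LEFT or RIGHT
    role: str  # INSIDE / OUTSIDE / "NA"
    t_heelstrike: float
    t_toeoff: float
    on_plate: bool
    plate_id: int | None = None

    @property
    def t_c(self) -> float:
        """Contact time (s)."""
        return self.t_toeoff - self.t_heelstrike


def lowpass_zero_lag(series: np.ndarray, cutoff: float, rate: float, order: int = 4) -> np.ndarray:
    """Zero-lag low-pass Butterworth filter (applied forward and backward).

    Parameters
    ----------
    series : array, shape (n,) or (n, k)
        Samples on a uniform grid at ``rate`` Hz; columns filtered independently.
    cutoff : float
        Cutoff frequency in Hz; must be below the Nyquist frequency.
    order : int
        Order of the underlying one-pass Butterworth design.
    """
    if not 0 < cutoff < rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={rate / 2} Hz)")
    series = np.asarray(series, dtype=float)
    if series.shape[0] <= 3 * order:
        raise ValueError("series too short for the requested filter order")
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, series, axis=0)


def detect_stance(
    time: np.ndarray,
    vgrf: np.ndarray,
    threshold: float = STANCE_THRESHOLD_N,
    min_duration: float = DEBOUNCE_S,
) -> list[StanceEvent]:
    """Detect stance phases as maximal intervals with vGRF > threshold.

    Heel-strike and toe-off are the threshold crossings bounding each
    interval, linearly interpolated between the bracketing samples (the
    sample grid alone would bias contact times by up to two samples);
    intervals shorter than ``min_duration`` are discarded as noise
    chatter.  Leg and role are unknown at this level and set to "NA".
    """
    vgrf = np.asarray(vgrf, dtype=float)
    above = vgrf > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)
    events = []
    for i0, i1 in zip(starts, ends):
        if i0 > 0:
            frac = (threshold - vgrf[i0 - 1]) / (vgrf[i0] - vgrf[i0 - 1])
            t_on = time[i0 - 1] + frac * (time[i0] - time[i0 - 1])
        else:
            t_on = time[0]
        if i1 < len(vgrf) - 1:
            frac = (vgrf[i1] - threshold) / (vgrf[i1] - vgrf[i1 + 1])
            t_off = time[i1] + frac * (time[i1 + 1] - time[i1])
        else:
            t_off = time[-1]
        if t_off - t_on >= min_duration:
            events.append(
                StanceEvent(
                    leg="NA",
                    role="NA",
                    t_heelstrike=float(t_on),
                    t_toeoff=float(t_off),
                    on_plate=True,
                )
            )
    return events


@dataclass
class StanceCalibration:
    """Per-subject marker heights at force-defined stance events (m)."""

    heel_height_hs: float
    met_height_to: float
    n_stances: int


class CalibrationError(RuntimeError):
    pass


def _sample_height(markers: MarkerSeries, label: str, t: float) -> float:
    z = markers.positions[label][:, 2]
    return float(np.interp(t, markers.time, z))


def build_stance_calibration(
    trials_with_events: list[tuple[Trial, list[StanceEvent]]],
) -> StanceCalibration:
    """Average heel/metatarsal heights at force heel-strike and toe-off.

    ``trials_with_events`` pairs each trial with its *on-plate* stance
    events whose ``leg`` has already been identified.
    """
    heel_h, met_h = [], []
    for trial, events in trials_with_events:
        side = {LEFT: ("LHEEL", "LMET"), RIGHT: ("RHEEL", "RMET")}
        for ev in events:
            if not ev.on_plate or ev.leg not in side:
                continue
            heel_lab, met_lab = side[ev.leg]
            heel_h.append(_sample_height(trial.markers, heel_lab, ev.t_heelstrike))
            met_h.append(_sample_height(trial.markers, met_lab, ev.t_toeoff))
    if not heel_h:
        raise CalibrationError(
            "no on-plate stances available: process on-plate steps before "
            "detecting off-plate events"
        )
    return StanceCalibration(
        heel_height_hs=float(np.mean(heel_h)),
        met_height_to=float(np.mean(met_h)),
        n_stances=len(heel_h),
    )


def _swing_regions(z, level, clearance):
    """Index ranges [j0, j1] where the marker is unambiguously airborne.

    Noise around the calibrated stance level cannot reach
    ``level + clearance``, so these regions anchor the event search.
    """
    high = np.asarray(z) >= level + clearance
    if not high.any():
        return []
    edges = np.diff(high.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if high[0]:
        starts.insert(0, 0)
    if high[-1]:
        ends.append(len(z) - 1)
    return list(zip(starts, ends))


def _fit_crossing(time, z, level, j_edge, ground_side, lo=0.004, hi=0.05):
    """Sub-frame crossing time of a foot-marker height through ``level``.

    Near the ground the height flattens to within sensor noise of the
    level, so the first-sample-below estimate jitters by whole frames.
    Instead the steep portion of the trajectory (``lo`` to ``hi`` metres
    above the level, where the slope dwarfs the noise) is fit with a line
    and extrapolated to the level.  ``ground_side`` is +1 when the ground
    phase follows the swing (heel-strike) and -1 when it precedes it
    (toe-off); ``j_edge`` is the adjacent airborne sample.
    """
    idx = []
    i = j_edge
    while 0 <= i < len(z) and z[i] <= level + hi:
        idx.append(i)
        i -= ground_side
    i = j_edge + ground_side
    while 0 <= i < len(z) and z[i] > level + lo:
        if z[i] <= level + hi:
            idx.append(i)
        i += ground_side
    if len(idx) < 2:
        i = min(max(i, 0), len(z) - 1)
        return float(time[i])
    idx = sorted(idx)
    slope, intercept = np.polyfit(time[idx], np.asarray(z)[idx], 1)
    if slope == 0:
        return None
    return float((level - intercept) / slope)


def detect_offplate_events(
    markers: MarkerSeries,
    calibration: StanceCalibration,
    leg: str,
    clearance: float = 0.02,
    min_stance: float = DEBOUNCE_S,
) -> list[StanceEvent]:
    """Detect stances of one leg from its foot-marker heights.

    Swing phases are located as regions where the marker height clears the
    calibrated level by ``clearance`` (beyond noise reach); heel-strike is
    the downward crossing of the heel height through the calibrated
    heel-strike level at the end of a heel swing, toe-off the upward
    crossing of the metatarsal height through the calibrated toe-off level
    at the start of a metatarsal swing.
    """
    if calibration is None:
        raise CalibrationError("missing calibration: process on-plate steps first")
    heel_lab, met_lab = ("LHEEL", "LMET") if leg == LEFT else ("RHEEL", "RMET")
    heel_z = markers.positions[heel_lab][:, 2]
    met_z = markers.positions[met_lab][:, 2]
    time = markers.time

    hs_times = []
    for _, j1 in _swing_regions(heel_z, calibration.heel_height_hs, clearance):
        t = _fit_crossing(time, heel_z, calibration.heel_height_hs, j1, +1)
        if t is not None and t >= time[0]:
            hs_times.append(t)
    to_times = []
    for j0, _ in _swing_regions(met_z, calibration.met_height_to, clearance):
        t = _fit_crossing(time, met_z, calibration.met_height_to, j0, -1)
        if t is not None and t <= time[-1]:
            to_times.append(t)

    events = []
    for t_hs in hs_times:
        later = [t for t in to_times if t > t_hs + min_stance]
        if not later:
            continue
        t_to = later[0]
        # Reject pairings that skipped a heel-strike (stance > half stride).
        next_hs = [t for t in hs_times if t > t_hs]
        if next_hs and t_to > next_hs[0]:
            continue
        events.append(
            StanceEvent(leg=leg, role="NA", t_heelstrike=t_hs, t_toeoff=t_to, on_plate=False)
        )
    return events


def assign_roles(events: list[StanceEvent], condition: str, direction: str) -> list[StanceEvent]:
    """Attach inside/outside roles from the sprinting direction.

    Running CCW about a centre on the runner's left makes the left leg the
    inside leg; CW mirrors this.  Straight trials have no role.
    """
    if condition != CURVE:
        return [replace(ev, role="NA") for ev in events]
    inside_leg = LEFT if direction == "CCW" else RIGHT
    return [
        replace(ev, role=INSIDE if ev.leg == inside_leg else OUTSIDE) for ev in events
    ]


def check_alternation(events: list[StanceEvent]) -> list[str]:
    """QC check: stances along a trial must alternate left/right."""
    flags = []
    ordered = sorted(events, key=lambda e: e.t_heelstrike)
    for a, b in zip(ordered, ordered[1:]):
        if a.leg == b.leg and a.leg != "NA":
            flags.append(
                f"non_alternating:{a.leg}@{a.t_heelstrike:.3f}s-{b.t_heelstrike:.3f}s"
            )
    return flags


def radar_smooth(time: np.ndarray, speed: np.ndarray, window: float, rate: float) -> np.ndarray:
    """Centred moving average of a radar speed trace.

    The window is ``round(window * rate)`` samples (15 samples for the
    0.32 s window at 47 Hz); edges use shrinking windows.  Averaging can
    only pull values toward the mean, so max(out) <= max(in).
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0:
        raise ValueError("empty radar series")
    n = int(round(window * rate))
    if n < 2:
        raise ValueError(f"window {window} s is under 2 samples at {rate} Hz")
    half_lo = (n - 1) // 2
    half_hi = n // 2
    out = np.empty_like(speed)
    csum = np.concatenate([[0.0], np.cumsum(speed)])
    for i in range(len(speed)):
        a = max(0, i - half_lo)
        b = min(len(speed), i + half_hi + 1)
        out[i] = (csum[b] - csum[a]) / (b - a)
    return out
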