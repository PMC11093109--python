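"""Centripetal/tangential force decomposition and stance-average metrics.

Horizontal plate-frame forces are rotated into a path-aligned frame: for
curve trials the rotation angle is the angle subtended at the curve centre
between the global-frame origin (the plate-pair centre) and the 3rd
metatarsal head marker at the time of peak vertical force; for straight
trials a fixed plate-path angle (14 deg) is used.  The centripetal axis
points toward the curve centre for both sprinting directions, so CCW and
CW trials pool without sign flips.

Stance-average forces are time averages over the stance interval
normalised by body weight; the resultant is the vector sum of the
stance-average centripetal and vertical components (the tangential
component is deliberately excluded), computed per trial from the two
averages rather than averaging instantaneous resultants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import StanceEvent
from .trial import CCW, CURVE, TrialMeta


@dataclass
class GrfSummary:
    cgrf_avg: float  # BW, positive toward the curve centre
    vgrf_avg: float  # BW
    rgrf_avg: float  # BW, sqrt(cgrf_avg**2 + vgrf_avg**2)
    rotation_angle: float  # deg
    propulsive_impulse: float  # N*s
    braking_impulse: float  # N*s
    t_peak_vgrf: float  # s


def rotation_angle(
    foot_point: tuple[float, float],
    curve_center: tuple[float, float],
    gcs_origin: tuple[float, float] = (0.0, 0.0),
    direction: str = CCW,
) -> float:
    """Signed angle (deg) at the curve centre between origin and foot rays.

    Positive when rotating the origin ray onto the foot ray follows the
    running direction.
    """
    cx, cy = curve_center
    a = np.array([gcs_origin[0] - cx, gcs_origin[1] - cy])
    b = np.array([foot_point[0] - cx, foot_point[1] - cy])
    if np.hypot(*a) == 0 or np.hypot(*b) == 0:
        raise ValueError("degenerate geometry: point coincides with the curve centre")
    ang = math.atan2(a[0] * b[1] - a[1] * b[0], float(a @ b))
    if direction != CCW:
        ang = -ang
    return math.degrees(ang)


def rotate_horizontal(
    fx: np.ndarray, fy: np.ndarray, angle_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Planar rotation of horizontal force components by ``angle_deg``.

    Per-sample horizontal magnitude is preserved exactly.  Returns the
    components in the rotated frame (x', y').
    """
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return c * fx + s * fy, -s * fx + c * fy


def path_axes(meta: TrialMeta, foot_point: tuple[float, float]) -> tuple[np.ndarray, np.ndarray, float]:
    """Centripetal and tangential unit vectors for one stance.

    For curves the centripetal axis runs horizontally from the foot point
    toward the curve centre and the tangential axis points along the
    running direction; the returned angle is the subtended rotation from
    the plate's nominal axes.  For straight trials the axes are the plate
    axes rotated by the fixed plate-path angle and "centripetal" denotes
    the mediolateral axis.
    """
    if meta.condition == CURVE:
        cx, cy = meta.curve_center
        c_hat = np.array([cx - foot_point[0], cy - foot_point[1]])
        c_hat /= np.hypot(*c_hat)
        # Forward = centripetal rotated -90 deg for CCW (centre on the left),
        # +90 deg for CW, so that it points along the direction of travel.
        if meta.direction == CCW:
            t_hat = np.array([c_hat[1], -c_hat[0]])
        else:
            t_hat = np.array([-c_hat[1], c_hat[0]])
        angle = rotation_angle(foot_point, meta.curve_center, (0.0, 0.0), meta.direction)
    else:
        a = math.radians(meta.plate_path_angle)
        t_hat = np.array([math.cos(a), math.sin(a)])
        c_hat = np.array([-t_hat[1], t_hat[0]])  # mediolateral, left of travel
        angle = meta.plate_path_angle
    return c_hat, t_hat, angle


def decompose_forces(
    fx: np.ndarray, fy: np.ndarray, meta: TrialMeta, foot_point: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Project horizontal forces onto the centripetal/tangential axes."""
    c_hat, t_hat, angle = path_axes(meta, foot_point)
    centripetal = fx * c_hat[0] + fy * c_hat[1]
    tangential = fx * t_hat[0] + fy * t_hat[1]
    return centripetal, tangential, angle


def _stance_window(time, f, t0, t1):
    """Samples inside [t0, t1] with linearly interpolated end points, so
    integrals cover the exact stance span rather than the nearest samples."""
    inner = (time > t0) & (time < t1)
    t = np.concatenate([[t0], time[inner], [t1]])
    y = np.concatenate([[np.interp(t0, time, f)], f[inner], [np.interp(t1, time, f)]])
    return t, y


def impulses(
    time: np.ndarray, tangential: np.ndarray, event: StanceEvent
) -> tuple[float, float]:
    """Propulsive (positive) and braking (magnitude of negative) impulses.

    Trapezoidal integration on the native sample grid over the stance.
    """
    t, f = _stance_window(time, tangential, event.t_heelstrike, event.t_toeoff)
    propulsive = float(np.trapezoid(np.clip(f, 0, None), t))
    braking = float(-np.trapezoid(np.clip(f, None, 0), t))
    return propulsive, braking


def stance_averages(
    time: np.ndarray,
    centripetal: np.ndarray,
    vertical: np.ndarray,
    tangential: np.ndarray,
    event: StanceEvent,
    body_mass: float,
    gravity: float,
    rotation_deg: float,
) -> GrfSummary:
    """Stance-average forces in body weights plus impulses for one stance."""
    if event.t_heelstrike < time[0] or event.t_toeoff > time[-1]:
        raise ValueError("stance truncated by the record boundary")
    bw = body_mass * gravity
    span = event.t_toeoff - event.t_heelstrike
    tc, c = _stance_window(time, centripetal, event.t_heelstrike, event.t_toeoff)
    tv, v = _stance_window(time, vertical, event.t_heelstrike, event.t_toeoff)
    cgrf = float(np.trapezoid(c, tc) / span / bw)
    vgrf = float(np.trapezoid(v, tv) / span / bw)
    prop, brake = impulses(time, tangential, event)
    return GrfSummary(
        cgrf_avg=cgrf,
        vgrf_avg=vgrf,
        rgrf_avg=math.hypot(cgrf, vgrf),
        rotation_angle=rotation_deg,
        propulsive_impulse=prop,
        braking_impulse=brake,
        t_peak_vgrf=float(tv[int(np.argmax(v))]),
    )
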