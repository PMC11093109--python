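"""Trial data model for curve-sprint recordings.

A :class:`Trial` bundles one maximum-effort sprint recording: metadata
(subject, condition, curve geometry, sampling rates), a force-plate series
in the plate frame, a labelled 3-D marker series in the global frame and,
for straight-path trials, a radar speed series.

Conventions
-----------
* Units are SI everywhere on disk and in memory (N, m, s, kg).  Forces are
  normalised to body weights only inside computations, never in storage.
* The global frame is right-handed with z up and its origin at the centre
  of the force-plate pair.  Plate axes coincide with the global horizontal
  axes; on the straight path the running direction makes a fixed angle
  (14 deg by default) with the plate tangential axis.
* The straight condition is encoded with an infinite radius so that model
  code can take the r -> inf limit naturally (JSON stores ``null``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Conditions
STRAIGHT = "straight"
CURVE = "curve"

#: Sprinting directions around the curve centre.
CCW = "CCW"
CW = "CW"
NA = "NA"

#: Sentinel radius for the straight condition.
INF_RADIUS = math.inf

#: Smallest regulation curve radius handled (innermost lane, 200 m track).
MIN_RADIUS = 17.2

#: Low-pass cutoff (Hz) used throughout processing; the force rate must
#: exceed twice this value for the filter to be well defined.
FILTER_CUTOFF_HZ = 50.0

PELVIS_LABELS = ("LIC", "RIC", "LASIS", "RASIS", "LPSIS", "RPSIS")
FOOT_LABELS = ("LMET", "RMET", "LHEEL", "RHEEL")
REQUIRED_LABELS = PELVIS_LABELS + FOOT_LABELS


class TrialValidationError(ValueError):
    """Raised with the full list of invariant breaches (never truncated)."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class TrialLoadError(OSError):
    """Raised when an on-disk trial is missing a required file."""


def _monotone_problems(time: np.ndarray, name: str) -> list[str]:
    """Report every row index where a time stamp fails to increase."""
    bad = np.flatnonzero(np.diff(time) <= 0)
    return [f"{name}: time not strictly increasing at row {int(i) + 1}" for i in bad]


@dataclass
class TrialMeta:
    trial_id: str
    subject_id: str
    body_mass: float  # kg
    condition: str  # STRAIGHT or CURVE
    radius: float = INF_RADIUS  # m; INF_RADIUS for straight
    direction: str = NA  # CCW / CW / NA
    curve_center: tuple[float, float] | None = None  # m, global frame
    plate_path_angle: float = 14.0  # deg, plate tangential axis vs path
    force_rate: float = 1000.0  # Hz
    marker_rate: float = 200.0  # Hz
    radar_rate: float = 47.0  # Hz
    gravity: float = 9.81  # m s^-2

    @property
    def body_weight(self) -> float:
        """Body weight m*g in newtons."""
        return self.body_mass * self.gravity

    def validate(self) -> list[str]:
        p: list[str] = []
        if not self.body_mass > 0:
            p.append(f"body_mass: must be > 0, got {self.body_mass}")
        if self.condition not in (STRAIGHT, CURVE):
            p.append(f"condition: unknown value {self.condition!r}")
        if self.condition == STRAIGHT:
            if not math.isinf(self.radius):
                p.append("radius: straight trials use the infinite-radius sentinel")
            if self.direction != NA:
                p.append("direction: must be NA for straight trials")
        else:
            if not (math.isfinite(self.radius) and self.radius >= MIN_RADIUS):
                p.append(
                    f"radius: curve radius must be finite and >= {MIN_RADIUS} m, "
                    f"got {self.radius}"
                )
            if self.direction not in (CCW, CW):
                p.append(f"direction: must be CCW or CW for curves, got {self.direction!r}")
            if self.curve_center is None:
                p.append("curve_center: required for curve trials")
        if not self.force_rate > 2 * FILTER_CUTOFF_HZ:
            p.append(
                f"force_rate: must exceed twice the {FILTER_CUTOFF_HZ:g} Hz "
                f"filter cutoff, got {self.force_rate}"
            )
        return p


@dataclass
class ForceSeries:
    """Three-axis force-plate series in the plate frame (fz vertical-up, N)."""

    time: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray

    def validate(self) -> list[str]:
        p: list[str] = []
        n = len(self.time)
        for name in ("fx", "fy", "fz"):
            if len(getattr(self, name)) != n:
                p.append(f"forces: {name} length {len(getattr(self, name))} != time length {n}")
        p += _monotone_problems(self.time, "forces")
        return p


@dataclass
class MarkerSeries:
    """Labelled 3-D marker positions (m) on a uniform time grid, global frame.

    ``positions`` maps a label to an (n, 3) array.  Non-finite samples are
    legal but flagged as gaps; they are never silently interpolated.
    """

    time: np.ndarray
    positions: dict[str, np.ndarray]

    def validate(self) -> list[str]:
        p: list[str] = []
        n = len(self.time)
        for label in REQUIRED_LABELS:
            if label not in self.positions:
                p.append(f"markers: required label {label} missing")
        for label, xyz in self.positions.items():
            if xyz.shape != (n, 3):
                p.append(f"markers: {label} shape {xyz.shape} != ({n}, 3)")
        p += _monotone_problems(self.time, "markers")
        return p

    def gap_labels(self) -> list[str]:
        """Labels containing non-finite samples (QC flag, not an error)."""
        return [lab for lab, xyz in self.positions.items() if not np.isfinite(xyz).all()]

    def pelvis_centroid(self) -> np.ndarray:
        """Unweighted mean of the six pelvis markers, the centre-of-mass proxy."""
        stack = np.stack([self.positions[lab] for lab in PELVIS_LABELS])
        return stack.mean(axis=0)


@dataclass
class RadarSeries:
    time: np.ndarray
    speed: np.ndarray  # m/s

    def validate(self) -> list[str]:
        p: list[str] = []
        if len(self.speed) != len(self.time):
            p.append("radar: speed and time lengths differ")
        if np.any(self.speed < 0):
            row = int(np.flatnonzero(self.speed < 0)[0])
            p.append(f"radar: negative speed at row {row}")
        p += _monotone_problems(self.time, "radar")
        return p


@dataclass
class Trial:
    meta: TrialMeta
    forces: ForceSeries
    markers: MarkerSeries
    radar: RadarSeries | None = None
    qc_flags: list[str] = field(default_factory=list)

    def validate(self) -> "Trial":
        """Check every invariant; raise with the full problem list on failure."""
        problems = self.meta.validate()
        problems += self.forces.validate()
        problems += self.markers.validate()
        if self.radar is not None:
            problems += self.radar.validate()
            if self.meta.condition != STRAIGHT:
                problems.append("radar: series present on a curve trial")
        gaps = self.markers.gap_labels()
        if gaps:
            self.qc_flags.append("marker_gaps:" + ",".join(sorted(gaps)))
        if problems:
            raise TrialValidationError(problems)
        return self
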