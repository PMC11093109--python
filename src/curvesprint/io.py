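"""On-disk format for trials and sessions.

One directory per trial, holding four plain-text files in a fixed dialect
(comma separated, '.' decimal, single header row, time in seconds first):

``meta.json``
    UTF-8 JSON, keys exactly as the :class:`~curvesprint.trial.TrialMeta`
    fields.  The straight condition stores ``radius: null``.
``forces.csv``
    time,fx,fy,fz — newtons in the plate frame.
``markers.csv``
    time plus ``<LABEL>_x/_y/_z`` columns — metres in the global frame.
``radar.csv``
    time,speed — present for straight trials only.

Floats are written with 15 significant digits so that a write/read
round-trip is the identity for practical purposes.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .trial import (
    INF_RADIUS,
    REQUIRED_LABELS,
    STRAIGHT,
    ForceSeries,
    MarkerSeries,
    RadarSeries,
    Trial,
    TrialLoadError,
    TrialMeta,
)

_FLOAT_FMT = "%.15g"
_META_FIELDS = (
    "trial_id",
    "subject_id",
    "body_mass",
    "condition",
    "radius",
    "direction",
    "curve_center",
    "plate_path_angle",
    "force_rate",
    "marker_rate",
    "radar_rate",
    "gravity",
)


def write_trial(trial: Trial, path: str | Path) -> Path:
    """Write a validated trial to ``path`` in the canonical dialect."""
    trial.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = trial.meta
    doc = {f: getattr(meta, f) for f in _META_FIELDS}
    doc["radius"] = None if math.isinf(meta.radius) else meta.radius
    doc["curve_center"] = None if meta.curve_center is None else list(meta.curve_center)
    (path / "meta.json").write_text(json.dumps(doc, indent=1), encoding="utf-8")

    f = trial.forces
    pd.DataFrame({"time": f.time, "fx": f.fx, "fy": f.fy, "fz": f.fz}).to_csv(
        path / "forces.csv", index=False, float_format=_FLOAT_FMT
    )

    m = trial.markers
    cols: dict[str, np.ndarray] = {"time": m.time}
    for label in sorted(m.positions):
        xyz = m.positions[label]
        for j, ax in enumerate("xyz"):
            cols[f"{label}_{ax}"] = xyz[:, j]
    pd.DataFrame(cols).to_csv(path / "markers.csv", index=False, float_format=_FLOAT_FMT)

    radar_path = path / "radar.csv"
    if trial.radar is not None:
        pd.DataFrame({"time": trial.radar.time, "speed": trial.radar.speed}).to_csv(
            radar_path, index=False, float_format=_FLOAT_FMT
        )
    elif radar_path.exists():
        radar_path.unlink()
    return path


def read_trial(path: str | Path) -> Trial:
    """Read and validate one trial directory.

    Missing files raise :class:`TrialLoadError` naming the file; invariant
    breaches raise :class:`~curvesprint.trial.TrialValidationError` with
    every problem enumerated.
    """
    path = Path(path)
    for required in ("meta.json", "forces.csv", "markers.csv"):
        if not (path / required).exists():
            raise TrialLoadError(f"missing file: {path / required}")

    doc = json.loads((path / "meta.json").read_text(encoding="utf-8"))
    meta = TrialMeta(
        trial_id=doc["trial_id"],
        subject_id=doc["subject_id"],
        body_mass=float(doc["body_mass"]),
        condition=doc["condition"],
        radius=INF_RADIUS if doc.get("radius") is None else float(doc["radius"]),
        direction=doc.get("direction", "NA"),
        curve_center=None if doc.get("curve_center") is None else tuple(doc["curve_center"]),
        plate_path_angle=float(doc.get("plate_path_angle", 14.0)),
        force_rate=float(doc.get("force_rate", 1000.0)),
        marker_rate=float(doc.get("marker_rate", 200.0)),
        radar_rate=float(doc.get("radar_rate", 47.0)),
        gravity=float(doc.get("gravity", 9.81)),
    )

    fdf = pd.read_csv(path / "forces.csv")
    forces = ForceSeries(
        time=fdf["time"].to_numpy(float),
        fx=fdf["fx"].to_numpy(float),
        fy=fdf["fy"].to_numpy(float),
        fz=fdf["fz"].to_numpy(float),
    )

    mdf = pd.read_csv(path / "markers.csv")
    labels = sorted({c[:-2] for c in mdf.columns if c.endswith(("_x", "_y", "_z"))})
    positions = {
        lab: np.column_stack([mdf[f"{lab}_{ax}"].to_numpy(float) for ax in "xyz"])
        for lab in labels
    }
    markers = MarkerSeries(time=mdf["time"].to_numpy(float), positions=positions)

    radar = None
    if (path / "radar.csv").exists():
        rdf = pd.read_csv(path / "radar.csv")
        radar = RadarSeries(time=rdf["time"].to_numpy(float), speed=rdf["speed"].to_numpy(float))

    return Trial(meta=meta, forces=forces, markers=markers, radar=radar).validate()


def write_session(trials: list[Trial], out_dir: str | Path) -> Path:
    """Write every trial of a session under ``out_dir/<trial_id>/``."""
    out_dir = Path(out_dir)
    for trial in trials:
        write_trial(trial, out_dir / trial.meta.trial_id)
    return out_dir


def read_session(session_dir: str | Path) -> list[Trial]:
    """Read every trial directory (one meta.json each) under ``session_dir``."""
    session_dir = Path(session_dir)
    trial_dirs = sorted(p.parent for p in session_dir.glob("*/meta.json"))
    if not trial_dirs:
        raise TrialLoadError(f"no trial directories under {session_dir}")
    return [read_trial(p) for p in trial_dirs]


def is_straight(trial: Trial) -> bool:
    return trial.meta.condition == STRAIGHT
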