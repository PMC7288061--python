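"""Columnar text I/O and run manifests.

All interchange files are comma-separated with a header row; angles are
written in degrees, positions and lengths in meters, time in seconds.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from physikin.data import MeasurementSeries, MotionTruth
from physikin.skeleton import JCP_NAMES, JOINT_NAMES, LENGTH_NAMES

_AXES = ("x", "y", "z")


def write_measurements(path, series: MeasurementSeries) -> None:
    cols = {"t": series.t}
    for j, name in enumerate(JCP_NAMES):
        for a, ax in enumerate(_AXES):
            cols[f"{name}_{ax}"] = series.positions[:, j, a]
    for j, name in enumerate(JCP_NAMES):
        cols[f"valid_{name}"] = series.validity[:, j].astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_measurements(path) -> MeasurementSeries:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas details vary
        raise ValueError(f"{path}: cannot parse ({exc})") from exc
    missing = [c for c in ["t"] + [f"{n}_{a}" for n in JCP_NAMES
                                   for a in _AXES] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing[:3]}...")
    t = df["t"].to_numpy()
    pos = np.empty((len(df), len(JCP_NAMES), 3))
    for j, name in enumerate(JCP_NAMES):
        for a, ax in enumerate(_AXES):
            pos[:, j, a] = df[f"{name}_{ax}"].to_numpy()
    valid_cols = [f"valid_{n}" for n in JCP_NAMES]
    if all(c in df.columns for c in valid_cols):
        validity = df[valid_cols].to_numpy().astype(bool)
    else:
        validity = None
    return MeasurementSeries(t=t, positions=pos, validity=validity)


def write_angles(path, t, theta_rad, lengths=None, n_active=None,
                 predicted_only=None) -> None:
    """Filter/reference output: time, 22 angles (deg), optional lengths
    (m) and per-frame constraint-activity count."""
    cols = {"t": np.asarray(t)}
    theta_deg = np.rad2deg(np.asarray(theta_rad))
    for j, name in enumerate(JOINT_NAMES):
        cols[f"theta_{j + 1}_{name}_deg"] = theta_deg[:, j]
    if lengths is not None:
        lengths = np.asarray(lengths)
        if lengths.ndim == 1:
            lengths = np.tile(lengths, (len(cols["t"]), 1))
        for k, name in enumerate(LENGTH_NAMES):
            cols[f"len_{name}_m"] = lengths[:, k]
    if n_active is not None:
        cols["n_active_constraints"] = np.asarray(n_active)
    if predicted_only is not None:
        cols["predicted_only"] = np.asarray(predicted_only).astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_angles(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (t, theta in radians)."""
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    cols = [c for c in df.columns if c.startswith("theta_")]
    cols.sort(key=lambda c: int(c.split("_")[1]))
    theta = np.deg2rad(df[cols].to_numpy())
    return t, theta


def write_truth(path, truth: MotionTruth) -> None:
    cols = {"t": truth.t}
    theta_deg = np.rad2deg(truth.theta)
    for j, name in enumerate(JOINT_NAMES):
        cols[f"theta_{j + 1}_{name}_deg"] = theta_deg[:, j]
    for a, ax in enumerate(_AXES):
        cols[f"root_{ax}_m"] = truth.root[:, a]
    pd.DataFrame(cols).to_csv(path, index=False)


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_manifest(path, command: str, params: dict,
                   outputs: list[str]) -> None:
    doc = {
        "command": command,
        "params": params,
        "config_hash": config_hash(params),
        "outputs": outputs,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
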