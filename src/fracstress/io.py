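"""Trajectory and result file I/O.

Trajectories travel as plain CSV with columns ``t,X,Y,Z`` (12
significant digits) plus a JSON sidecar (``<path>.json``) holding the
configuration that produced them, so every output file is reproducible
from its own metadata.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .solver import SolverConfig, Trajectory

__all__ = ["write_trajectory", "read_trajectory", "TrajectoryParseError"]

COLUMNS = ("t", "X", "Y", "Z")


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; the message names the offending line."""


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_trajectory(path, traj: Trajectory, extra_config: dict | None = None) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "t": traj.times,
            "X": traj.states[:, 0],
            "Y": traj.states[:, 1],
            "Z": traj.states[:, 2],
        }
    )
    frame.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "orders": [float(q) for q in traj.orders],
        "diverged": bool(traj.diverged),
        "n_samples": len(traj),
    }
    if traj.config is not None:
        cfg = dataclasses.asdict(traj.config)
        cfg["initial_state"] = [float(v) for v in np.asarray(cfg["initial_state"])]
        meta["solver"] = cfg
    if extra_config:
        meta["run"] = extra_config
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TrajectoryParseError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: line 1: missing column(s) {missing}")
    for col in COLUMNS:
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise TrajectoryParseError(f"{path}: line {line}: non-numeric value in {col!r}")
        if frame[col].isna().any():
            line = int(frame[col].isna().idxmax()) + 2
            raise TrajectoryParseError(f"{path}: line {line}: empty value in {col!r}")
    times = frame["t"].to_numpy(dtype=float)
    if len(times) > 2:
        dt = np.diff(times)
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(1.0, abs(dt[0])):
            line = int(np.argmax(np.abs(dt - dt[0]))) + 3
            raise TrajectoryParseError(f"{path}: line {line}: non-uniform time grid")
    states = frame[["X", "Y", "Z"]].to_numpy(dtype=float)
    orders = np.array([1.0, 1.0, 1.0])
    diverged = False
    config = None
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        orders = np.asarray(meta.get("orders", orders), dtype=float)
        diverged = bool(meta.get("diverged", False))
        if "solver" in meta:
            config = SolverConfig(**meta["solver"])
    return Trajectory(times=times, states=states, orders=orders, diverged=diverged, config=config)
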