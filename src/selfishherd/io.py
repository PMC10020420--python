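"""Trajectory persistence: compact binary container, CSV interchange, XYZ dumps.

The native container is an ``.npz`` archive with an embedded schema version
and provenance (config dict, hash, seed); long runs need compact storage, but
every trajectory also exports to a tidy columnar CSV (one row per agent per
frame) and an XYZ-style frame dump for external viewers.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "SCHEMA_VERSION", "TrajectoryFormatError",
    "write_trajectory", "read_trajectory",
    "trajectory_to_frame", "write_trajectory_csv", "read_trajectory_csv",
    "write_xyz",
]

SCHEMA_VERSION = 1

_ARRAYS = ("positions", "headings", "areas", "nn_dist", "r_shh", "r_prox", "actions")


class TrajectoryFormatError(IOError):
    """Raised for version mismatches or corrupted trajectory files."""


def write_trajectory(traj: Trajectory, path) -> None:
    """Lossless binary round trip of all trajectory arrays plus provenance."""
    meta = json.dumps({"schema": SCHEMA_VERSION, "delta": traj.delta, "config": traj.config})
    np.savez_compressed(path, __meta__=meta, **{k: getattr(traj, k) for k in _ARRAYS})


def read_trajectory(path) -> Trajectory:
    try:
        with np.load(path, allow_pickle=False) as data:
            if "__meta__" not in data:
                raise TrajectoryFormatError(f"{path}: missing trajectory header")
            meta = json.loads(str(data["__meta__"]))
            if meta.get("schema") != SCHEMA_VERSION:
                raise TrajectoryFormatError(
                    f"{path}: schema version {meta.get('schema')} != {SCHEMA_VERSION}"
                )
            arrays = {k: data[k] for k in _ARRAYS}
    except (OSError, ValueError, KeyError) as exc:
        if isinstance(exc, TrajectoryFormatError):
            raise
        raise TrajectoryFormatError(f"{path}: not a readable trajectory file: {exc}") from exc
    return Trajectory(**arrays, delta=float(meta["delta"]), config=meta.get("config", {}))


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy per-agent per-frame table: t, agent, x, y, theta, action, rewards, area."""
    T, n = traj.n_frames, traj.n_agents
    t_idx = np.repeat(np.arange(T), n)
    agent = np.tile(np.arange(n), T)
    # the final frame has no action; mark it -1
    actions = np.vstack([traj.actions, np.full((1, n), -1, dtype=int)]) if T else traj.actions
    return pd.DataFrame({
        "t": t_idx,
        "agent": agent,
        "x": traj.positions[..., 0].ravel(),
        "y": traj.positions[..., 1].ravel(),
        "theta": traj.headings.ravel(),
        "action": actions.ravel(),
        "r_shh": traj.r_shh.ravel(),
        "r_prox": traj.r_prox.ravel(),
        "area": traj.areas.ravel(),
        "nn_dist": traj.nn_dist.ravel(),
    })


def write_trajectory_csv(traj: Trajectory, path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False)


def read_trajectory_csv(path, delta: float = 10.0) -> Trajectory:
    """Rebuild a Trajectory from the tidy CSV (inverse of write_trajectory_csv)."""
    df = pd.read_csv(path)
    T = int(df["t"].max()) + 1
    n = int(df["agent"].max()) + 1
    df = df.sort_values(["t", "agent"])

    def grid(col):
        return df[col].to_numpy().reshape(T, n)

    return Trajectory(
        positions=np.stack([grid("x"), grid("y")], axis=-1),
        headings=grid("theta"),
        areas=grid("area"),
        nn_dist=grid("nn_dist"),
        r_shh=grid("r_shh"),
        r_prox=grid("r_prox"),
        actions=grid("action")[:-1].astype(int),
        delta=delta,
    )


def write_xyz(traj: Trajectory, path) -> None:
    """XYZ-style frame dump (x, y, heading as a pseudo-z) for external viewers."""
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"{traj.n_agents}\nframe {t}\n")
            for i in range(traj.n_agents):
                x, y = traj.positions[t, i]
                fh.write(f"A {x:.6f} {y:.6f} {traj.headings[t, i]:.6f}\n")
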