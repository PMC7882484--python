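"""CSV formats, sidecar metadata, and run manifests.

Trajectories are plain comma-separated text with header
``t,x,y,theta,hit_left,hit_right`` and one row per 20 Hz sample; trial
metadata (seed, outcome, search time, config hash) lives in a JSON sidecar
next to the CSV.  All formats round-trip losslessly at the written precision
and malformed files are rejected with the offending line number.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .episode import TRAJECTORY_COLUMNS, Trajectory

__all__ = [
    "TrajectoryFormatError", "write_trajectory", "read_trajectory",
    "write_rewards", "read_rewards", "write_maneuvers", "read_maneuvers",
    "file_checksum", "RunManifest",
]

REWARD_COLUMNS = ["t", "S", "dS", "EdS", "p_star", "hit", "cum_hits", "hit_rate"]
MANEUVER_COLUMNS = ["t", "tau_b", "v", "omega", "temporal", "kinematic", "match"]


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file (message includes the line number)."""


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_trajectory(traj: Trajectory, path, config_hash: str | None = None) -> None:
    """Write a trajectory CSV plus its JSON metadata sidecar."""
    path = Path(path)
    df = traj.samples[TRAJECTORY_COLUMNS]
    out = df.copy()
    for col in ("t", "x", "y", "theta"):
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    for col in ("hit_left", "hit_right"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, lineterminator="\n")
    meta = {"seed": traj.seed, "outcome": traj.outcome,
            "search_time": traj.search_time}
    if config_hash is not None:
        meta["config_hash"] = config_hash
    _sidecar(path).write_text(json.dumps(meta, sort_keys=True, indent=1))


def read_trajectory(path) -> Trajectory:
    """Read and validate a trajectory CSV (and its sidecar, if present)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header != TRAJECTORY_COLUMNS:
            missing = set(TRAJECTORY_COLUMNS) - set(header)
            raise TrajectoryFormatError(
                f"{path}: line 1: bad header, missing columns {sorted(missing)}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 6:
                raise TrajectoryFormatError(
                    f"{path}: line {lineno}: expected 6 fields, got {len(parts)}")
            try:
                t, x, y, th = (float(parts[0]), float(parts[1]),
                               float(parts[2]), float(parts[3]))
                hl, hr = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"{path}: line {lineno}: {exc}") from exc
            if hl not in (0, 1) or hr not in (0, 1):
                raise TrajectoryFormatError(
                    f"{path}: line {lineno}: hit flags must be 0 or 1")
            rows.append((t, x, y, th, hl, hr))
    if not rows:
        raise TrajectoryFormatError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    tvals = df["t"].to_numpy()
    bad = np.flatnonzero(np.diff(tvals) <= 0)
    if bad.size:
        raise TrajectoryFormatError(
            f"{path}: line {int(bad[0]) + 3}: t is not strictly increasing")
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return Trajectory(df, meta.get("outcome", "unknown"),
                      float(meta.get("search_time", float("nan"))),
                      int(meta.get("seed", -1)))


def write_rewards(df: pd.DataFrame, path) -> None:
    df[REWARD_COLUMNS].to_csv(path, index=False, float_format="%.9g",
                              lineterminator="\n")


def read_rewards(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REWARD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing reward columns {sorted(missing)}")
    return df


def write_maneuvers(df: pd.DataFrame, path) -> None:
    df[MANEUVER_COLUMNS].to_csv(path, index=False, float_format="%.9g",
                                lineterminator="\n")


def read_maneuvers(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANEUVER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing maneuver columns {sorted(missing)}")
    return df


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    stages: dict = dataclasses.field(default_factory=dict)
    created: str = ""

    def add_stage(self, name: str, inputs: list[str], outputs: list[str]) -> None:
        self.stages[name] = {
            "inputs": [str(p) for p in inputs],
            "outputs": {str(p): file_checksum(p) for p in outputs},
        }

    def write(self, path) -> None:
        from . import __version__
        payload = {"config_hash": self.config_hash, "seed": self.seed,
                   "version": __version__, "stages": self.stages,
                   "created": self.created or _dt.datetime.now().isoformat()}
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @staticmethod
    def read(path) -> dict:
        return json.loads(Path(path).read_text())
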