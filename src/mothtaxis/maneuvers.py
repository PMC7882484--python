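"""Temporal and kinematic maneuver labelling and the match/mismatch scheme.

Every sample of a trajectory is labelled twice:

* temporal scheme — from the blank duration tau_b (time since the last gated
  odor hit) alone: Surge if tau_b <= 500 ms, Rotate if tau_b > 500 ms, Stop
  before the first hit;
* kinematic scheme — from tau_b plus the linear and angular speeds (v, omega)
  estimated from the pose by central differences, evaluated in clause order:

  1. Surge   if tau_b <= 500 ms and v > 0
  2. Rotate  if tau_b > 200 ms and |omega| > 0
  3. Surge   if tau_b > 200 ms and |omega| < 5 deg/s   (slow, straight drift)
  4. Stop    otherwise (including pre-first-hit samples)

The rotate clause opens at the 200 ms bound so that rotations inside the
200-500 ms post-hit window — where the temporal model predicts a surge —
are classified kinematically as rotations; these are exactly the
"mismatching" samples.  A sample is *matching* when both schemes agree on a
non-Stop label, *mismatching* when the kinematics say Rotate while the
temporal model says Surge, and *excluded* otherwise (Stop under either
scheme, or the impossible-by-construction Rotate/Surge combination, which
requires omega == 0 exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .belief import gated_hits
from .config import ClassifyConfig, wrap_angle

__all__ = [
    "Label", "ManeuverMatrix",
    "blank_durations", "classify_temporal", "classify_kinematic",
    "match_labels", "pose_velocities", "classify_trajectory",
    "maneuver_matrix", "cohort_matrix",
]

SURGE, ROTATE, STOP = "Surge", "Rotate", "Stop"
MATCH, MISMATCH, EXCLUDED = "match", "mismatch", "excluded"
Label = str

MANEUVER_COLUMNS = ["t", "tau_b", "v", "omega", "temporal", "kinematic", "match"]


def blank_durations(t: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Per-sample blank duration tau_b = t - (time of most recent gated hit).

    ``hits`` must already be capture-gated.  Samples before the first hit get
    NaN (undefined); a hit sample itself has tau_b = 0.
    """
    t = np.asarray(t, dtype=float)
    hits = np.asarray(hits, dtype=bool)
    # forward-fill the index of the most recent hit
    idx = np.where(hits, np.arange(t.size), -1)
    idx = np.maximum.accumulate(idx)
    tau = np.full(t.size, np.nan)
    seen = idx >= 0
    tau[seen] = t[seen] - t[idx[seen]]
    return tau


def classify_temporal(tau_b: float, config: ClassifyConfig | None = None) -> Label:
    """Temporal label from the blank duration alone."""
    cfg = config or ClassifyConfig()
    if tau_b is None or (isinstance(tau_b, float) and math.isnan(tau_b)):
        return STOP
    if tau_b <= cfg.surge_blank_max:
        return SURGE
    return ROTATE


def classify_kinematic(tau_b: float, v: float, omega: float,
                       config: ClassifyConfig | None = None) -> Label:
    """Kinematic label from blank duration, linear speed (mm/s) and angular
    speed (deg/s), evaluated in clause order (see module docstring)."""
    cfg = config or ClassifyConfig()
    if tau_b is None or (isinstance(tau_b, float) and math.isnan(tau_b)):
        return STOP
    if tau_b <= cfg.surge_blank_max and v > cfg.min_speed:
        return SURGE
    if tau_b > cfg.rotate_blank_min and abs(omega) > 0.0:
        return ROTATE
    if tau_b > cfg.rotate_blank_min and abs(omega) < cfg.slow_omega_max:
        return SURGE
    return STOP


def match_labels(temporal: Label, kinematic: Label) -> str:
    """Match status of one sample from its two labels."""
    if temporal == kinematic and temporal != STOP:
        return MATCH
    if kinematic == ROTATE and temporal == SURGE:
        return MISMATCH
    return EXCLUDED


def pose_velocities(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                    theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear speed (mm/s) and angular speed (deg/s) by central differences
    of the pose (one-sided at the endpoints)."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = t.size
    if n < 2:
        raise ValueError("need at least two samples")
    i_next = np.minimum(np.arange(n) + 1, n - 1)
    i_prev = np.maximum(np.arange(n) - 1, 0)
    dt = t[i_next] - t[i_prev]
    v = np.hypot(x[i_next] - x[i_prev], y[i_next] - y[i_prev]) / dt
    dth = np.array([wrap_angle(d) for d in theta[i_next] - theta[i_prev]])
    omega = np.degrees(dth) / dt
    return v, omega


def classify_trajectory(traj_df: pd.DataFrame, theta_src: float = 0.0,
                        config: ClassifyConfig | None = None) -> pd.DataFrame:
    """Label every sample of a trajectory; returns the maneuver table
    ``t, tau_b, v, omega, temporal, kinematic, match``."""
    cfg = config or ClassifyConfig()
    t = traj_df["t"].to_numpy(dtype=float)
    hits = gated_hits(traj_df, theta_src)
    tau = blank_durations(t, hits)
    v, omega = pose_velocities(t, traj_df["x"].to_numpy(),
                               traj_df["y"].to_numpy(),
                               traj_df["theta"].to_numpy())
    temporal = [classify_temporal(tb, cfg) for tb in tau]
    kinematic = [classify_kinematic(tb, vi, wi, cfg)
                 for tb, vi, wi in zip(tau, v, omega)]
    match = [match_labels(a, b) for a, b in zip(temporal, kinematic)]
    return pd.DataFrame({"t": t, "tau_b": tau, "v": v, "omega": omega,
                         "temporal": temporal, "kinematic": kinematic,
                         "match": match})


@dataclass
class ManeuverMatrix:
    """Normalized 2x2 maneuver counts, (kinematic in rows) x (temporal in
    columns), over {Surge, Rotate}, plus the excluded fraction.

    Cells are counts divided by the *total* number of samples, so the four
    included cells and the excluded fraction sum to one.
    """

    cells: np.ndarray          # [[SS, SR], [RS, RR]] kinematic x temporal
    excluded_fraction: float
    n_samples: int

    def cell(self, kinematic: Label, temporal: Label) -> float:
        i = {SURGE: 0, ROTATE: 1}[kinematic]
        j = {SURGE: 0, ROTATE: 1}[temporal]
        return float(self.cells[i, j])


def maneuver_matrix(records: pd.DataFrame) -> ManeuverMatrix:
    """Normalized maneuver matrix of one trial's maneuver table."""
    if len(records) == 0:
        raise ValueError("empty record list")
    total = len(records)
    cells = np.zeros((2, 2))
    included = 0
    for i, kin in enumerate((SURGE, ROTATE)):
        for j, temp in enumerate((SURGE, ROTATE)):
            c = int(((records["kinematic"] == kin)
                     & (records["temporal"] == temp)).sum())
            cells[i, j] = c
            included += c
    if included == 0:
        raise ValueError("all samples excluded: no Surge/Rotate labels")
    return ManeuverMatrix(cells / total, (total - included) / total, total)


def cohort_matrix(per_trial: list[ManeuverMatrix]) -> dict:
    """Cohort mean +/- sd of each matrix cell across trials."""
    stack = np.stack([m.cells for m in per_trial])
    excl = np.array([m.excluded_fraction for m in per_trial])
    sd = stack.std(axis=0, ddof=1) if len(per_trial) > 1 else np.zeros((2, 2))
    return {
        "mean": stack.mean(axis=0),
        "sd": sd,
        "excluded_mean": float(excl.mean()),
        "excluded_sd": float(excl.std(ddof=1)) if len(per_trial) > 1 else 0.0,
        "n_trials": len(per_trial),
    }
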