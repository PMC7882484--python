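"""Closed-loop virtual experiment: plume, sensing, gating, policy, pose.

Each episode runs the virtual-reality loop at the arena sampling rate:
advance the plume, sense both antennae, gate hits by the upwind-facing
capture condition, feed the blank duration to the programmed-behaviour
policy, and integrate the pose by forward Euler.  The episode terminates on
reaching the goal radius around the source (success) or at the time limit
(timeout) and is fully reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .belief import capture_gate
from .config import ArenaConfig, MothPolicyConfig, PlumeConfig, wrap_angle
from .plume import PlumeState, sense, step_plume
from .policy import PolicyState, programmed_policy

__all__ = ["Trajectory", "CohortSummary", "run_episode", "generate_cohort",
           "cohort_seeds"]

TRAJECTORY_COLUMNS = ["t", "x", "y", "theta", "hit_left", "hit_right"]


@dataclass
class Trajectory:
    """One trial: per-sample pose + raw antenna hits, outcome and metadata.

    ``samples`` holds columns ``t, x, y, theta, hit_left, hit_right``; hits
    are the raw (ungated) antenna detections so that downstream stages can
    re-apply the capture gate from the stored heading.
    """

    samples: pd.DataFrame
    outcome: str               # "success" | "timeout"
    search_time: float         # s (time of goal entry, or time_limit)
    seed: int

    @property
    def success(self) -> bool:
        return self.outcome == "success"

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class CohortSummary:
    n_trials: int
    n_success: int
    success_rate_pct: float
    mean_search_time: float    # over successful trials (nan if none)
    sd_search_time: float
    search_times: list[float] = field(default_factory=list)


def run_episode(arena: ArenaConfig, plume_cfg: PlumeConfig,
                policy_cfg: MothPolicyConfig, seed: int) -> Trajectory:
    """Simulate one closed-loop trial and return its trajectory."""
    x0, y0, th0 = arena.start_pose_global()
    if not arena.contains(x0, y0):
        raise ValueError(f"start pose ({x0}, {y0}) outside the arena")
    rng = np.random.default_rng(seed)
    dt = arena.dt
    sx, sy = arena.source_pos

    plume = PlumeState()
    pol_state = PolicyState()
    x, y, th = x0, y0, th0
    t = 0.0
    last_hit: float | None = None
    rows: list[tuple] = []
    outcome = "timeout"
    search_time = arena.time_limit

    for i in range(arena.n_steps + 1):
        t = i * dt
        plume = step_plume(plume, plume_cfg, arena, dt, rng)
        hl, hr = sense(plume, (x, y, th), policy_cfg.antenna_offset)
        rows.append((t, x, y, th, int(hl), int(hr)))
        if math.hypot(x - sx, y - sy) <= arena.goal_radius:
            outcome = "success"
            search_time = t
            break
        if i == arena.n_steps:
            break
        if (hl or hr) and capture_gate(th, arena.wind_angle):
            last_hit = t
            pol_state.reset_on_hit(rng)
        tau_b = None if last_hit is None else t - last_hit
        v, omega, pol_state = programmed_policy(pol_state, tau_b, policy_cfg, rng)
        x += v * math.cos(th) * dt
        y += v * math.sin(th) * dt
        th = wrap_angle(th + omega * dt)
        x = min(max(x, 0.0), arena.length_x)
        y = min(max(y, -arena.width_y / 2.0), arena.width_y / 2.0)

    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return Trajectory(df, outcome, search_time, int(seed))


def cohort_seeds(base_seed: int, n_trials: int) -> list[int]:
    """Stable per-trial seeds derived from a base seed (each < 2**31)."""
    ss = np.random.SeedSequence(int(base_seed))
    return [int(s % (2 ** 31)) for s in ss.generate_state(n_trials)]


def generate_cohort(n_trials: int, arena: ArenaConfig, plume_cfg: PlumeConfig,
                    policy_cfg: MothPolicyConfig, base_seed: int
                    ) -> tuple[list[Trajectory], CohortSummary]:
    """Run ``n_trials`` independent episodes with derived seeds.

    The summary reports the success count, the success rate as a percentage,
    and the mean +/- sd search time over the successful trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    trials = [run_episode(arena, plume_cfg, policy_cfg, s)
              for s in cohort_seeds(base_seed, n_trials)]
    return trials, summarize_cohort(trials)


def summarize_cohort(trials: list[Trajectory]) -> CohortSummary:
    times = [tr.search_time for tr in trials if tr.success]
    n_succ = len(times)
    return CohortSummary(
        n_trials=len(trials),
        n_success=n_succ,
        success_rate_pct=100.0 * n_succ / len(trials),
        mean_search_time=float(np.mean(times)) if times else float("nan"),
        sd_search_time=float(np.std(times, ddof=1)) if n_succ > 1 else 0.0 if n_succ else float("nan"),
        search_times=times,
    )
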