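"""Programmed-behaviour policy of the walking silkmoth.

The moth is motionless until its first odor hit.  Each (gated) hit resets the
blank duration tau_b to zero and restarts the maneuver sequence:

* surge   (tau_b <= surge_duration): straight forward run, omega = 0;
* zigzag  (next zigzag_phase_duration seconds): forward motion with
  alternating-sign constant turning, switching sign every leg;
* loop    (afterwards, until the next hit): constant-sign turning.

With probability ``deviation_rate`` per sample the commanded action is
replaced by a stochastic pure rotation (v = 0, |omega| uniform in the
configured deg/s bounds, random sign) — the controllable source of
"explorative" deviations from the programmed model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import MothPolicyConfig

__all__ = ["PolicyState", "programmed_policy"]

_DEG = math.pi / 180.0


@dataclass
class PolicyState:
    """Per-trial mutable policy state: the turning sign drawn at each hit."""

    turn_sign: int = 1

    def reset_on_hit(self, rng: np.random.Generator) -> None:
        self.turn_sign = 1 if rng.random() < 0.5 else -1


def programmed_policy(state: PolicyState, tau_b: float | None,
                      config: MothPolicyConfig,
                      rng: np.random.Generator) -> tuple[float, float, PolicyState]:
    """Return the commanded (v mm/s, omega rad/s) for the current sample.

    ``tau_b`` is the blank duration (seconds since the last gated hit), or
    ``None`` before the first hit, in which case the moth stays still and no
    deviation can occur.
    """
    if tau_b is None:
        return 0.0, 0.0, state
    if tau_b < 0:
        raise ValueError("tau_b must be >= 0")

    if config.deviation_rate > 0 and rng.random() < config.deviation_rate:
        mag = rng.uniform(config.deviation_omega_min, config.deviation_omega_max)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return 0.0, sign * mag * _DEG, state

    if tau_b <= config.surge_duration:
        return config.surge_speed, 0.0, state
    t_z = tau_b - config.surge_duration
    if t_z <= config.zigzag_phase_duration:
        leg = int(t_z / config.zigzag_leg_duration)
        sign = state.turn_sign * (1 if leg % 2 == 0 else -1)
        return config.zigzag_speed, sign * config.zigzag_turn_rate * _DEG, state
    # loop: keep turning in the direction the zigzag ended with
    n_legs = int(config.zigzag_phase_duration / config.zigzag_leg_duration)
    sign = state.turn_sign * (1 if n_legs % 2 == 0 else -1)
    return config.loop_speed, sign * config.loop_turn_rate * _DEG, state
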