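"""Stochastic puff-based odor plume.

The plume is a set of circular puffs emitted at the source as a Poisson
process, advected downwind at the mean wind speed, meandering laterally as a
Gaussian random walk, growing linearly in radius, and removed after a fixed
lifetime or once they leave the arena.  This parametric process reproduces the
sporadic, intermittent hit structure of a turbulent plume with a handful of
interpretable parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ArenaConfig, PlumeConfig

__all__ = ["PlumeState", "step_plume", "sense", "antenna_positions"]


@dataclass
class PlumeState:
    """Live puffs as parallel arrays (centers (n,2) mm, radii mm, ages s)."""

    centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    radii: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ages: np.ndarray = field(default_factory=lambda: np.zeros(0))
    intensities: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_puffs(self) -> int:
        return self.centers.shape[0]

    def copy(self) -> "PlumeState":
        return PlumeState(self.centers.copy(), self.radii.copy(),
                          self.ages.copy(), self.intensities.copy())


def step_plume(state: PlumeState, config: PlumeConfig, arena: ArenaConfig,
               dt: float, rng: np.random.Generator) -> PlumeState:
    """Advance the plume by ``dt`` seconds and return the new state.

    Existing puffs are advected downwind by ``wind_speed * dt`` with lateral
    Gaussian meander of standard deviation ``lateral_meander_sd * sqrt(dt)``,
    grown by ``growth_rate * dt`` and aged; puffs older than ``lifetime`` or
    entirely outside the (puff-radius padded) arena are removed.  New puffs
    are emitted at the source as a Poisson process with rate
    ``emission_rate``.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    wind = arena.wind_speed_mm
    ca, sa = math.cos(arena.wind_angle), math.sin(arena.wind_angle)

    centers = state.centers.copy()
    radii = state.radii + config.growth_rate * dt
    ages = state.ages + dt
    intens = state.intensities.copy()
    n = centers.shape[0]
    if n:
        # downwind advection + lateral (cross-wind) Gaussian meander
        meander = rng.normal(0.0, config.lateral_meander_sd * math.sqrt(dt), size=n)
        centers[:, 0] += wind * dt * ca - meander * sa
        centers[:, 1] += wind * dt * sa + meander * ca
        alive = ages <= config.lifetime
        alive &= centers[:, 0] + radii >= 0.0
        alive &= centers[:, 0] - radii <= arena.length_x
        alive &= np.abs(centers[:, 1]) - radii <= arena.width_y / 2.0
        centers, radii, ages, intens = (centers[alive], radii[alive],
                                        ages[alive], intens[alive])

    n_new = int(rng.poisson(config.emission_rate * dt)) if config.emission_rate > 0 else 0
    if n_new:
        src = np.asarray(arena.source_pos, dtype=float)
        centers = np.vstack([centers, np.tile(src, (n_new, 1))])
        radii = np.concatenate([radii, np.full(n_new, config.initial_radius)])
        ages = np.concatenate([ages, np.zeros(n_new)])
        intens = np.concatenate([intens, np.ones(n_new)])
    return PlumeState(centers, radii, ages, intens)


def antenna_positions(pose: tuple[float, float, float],
                      antenna_offset: float) -> tuple[np.ndarray, np.ndarray]:
    """Left/right antenna points: the head offset by +/-offset normal to theta."""
    x, y, th = pose
    nx, ny = -math.sin(th), math.cos(th)  # left normal
    left = np.array([x + antenna_offset * nx, y + antenna_offset * ny])
    right = np.array([x - antenna_offset * nx, y - antenna_offset * ny])
    return left, right


def sense(state: PlumeState, pose: tuple[float, float, float],
          antenna_offset: float) -> tuple[bool, bool]:
    """Binary per-antenna detection: a hit iff the antenna point lies strictly
    inside any puff disc."""
    if not all(math.isfinite(v) for v in pose):
        raise ValueError("pose must be finite")
    if state.n_puffs == 0:
        return (False, False)
    left, right = antenna_positions(pose, antenna_offset)
    d_left = np.hypot(state.centers[:, 0] - left[0], state.centers[:, 1] - left[1])
    d_right = np.hypot(state.centers[:, 0] - right[0], state.centers[:, 1] - right[1])
    return (bool(np.any(d_left < state.radii)), bool(np.any(d_right < state.radii)))
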