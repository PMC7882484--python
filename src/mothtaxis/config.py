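"""Configuration objects for the virtual arena, plume, moth policy and analysis.

All geometry is in millimetres, time in seconds and angles in radians
(counter-clockwise from the +x axis, wrapped to (-pi, pi]) unless a field says
otherwise.  Angular-velocity thresholds and turn rates are given in deg/s to
match the behavioural literature.  The defaults reproduce the reference
experiment: a 350 x 200 mm arena with wind blowing along +x at 0.1 m/s, the
pheromone source at the origin with a 35 mm goal radius, the moth starting at
(180, 0) with a 180 s limit sampled at 20 Hz.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "ArenaConfig",
    "PlumeConfig",
    "MothPolicyConfig",
    "LikelihoodConfig",
    "ClassifyConfig",
    "AnalysisConfig",
    "PipelineConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "config_hash",
    "wrap_angle",
]


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


def wrap_angle(theta: float) -> float:
    """Wrap an angle (rad) into (-pi, pi]."""
    return math.pi - (math.pi - theta) % (2.0 * math.pi)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _finite(*values: float) -> bool:
    return all(math.isfinite(float(v)) for v in values)


@dataclass
class ArenaConfig:
    """Arena geometry, wind and trial protocol.

    ``heading_frame`` selects the reference axis of the heading component of
    ``start_pose``: ``"upwind"`` (default) measures it counter-clockwise from
    the upwind direction (so an angle of 0 faces the source under wind along
    +x), ``"wind"`` measures it from the +x axis directly.  The positions are
    always in the global frame with the source at ``source_pos``.
    """

    length_x: float = 350.0          # mm, downwind extent (x in [0, length_x])
    width_y: float = 200.0           # mm (y in [-width_y/2, width_y/2])
    source_pos: tuple[float, float] = (0.0, 0.0)
    goal_radius: float = 35.0        # mm
    start_pose: tuple[float, float, float] = (180.0, 0.0, -math.pi / 6.0)
    time_limit: float = 180.0        # s
    sample_rate: float = 20.0        # Hz
    wind_speed: float = 0.1          # m/s, along wind_angle
    wind_angle: float = 0.0          # rad, direction the wind blows toward
    heading_frame: str = "upwind"    # "upwind" | "wind"

    def __post_init__(self) -> None:
        _require(_finite(self.length_x, self.width_y, self.goal_radius,
                         self.time_limit, self.sample_rate, self.wind_speed,
                         self.wind_angle, *self.source_pos, *self.start_pose),
                 "arena: non-finite value")
        _require(self.goal_radius > 0, "arena.goal_radius must be > 0")
        _require(self.sample_rate > 0, "arena.sample_rate must be > 0")
        _require(self.time_limit > 0, "arena.time_limit must be > 0")
        _require(self.length_x > 0 and self.width_y > 0, "arena extents must be > 0")
        _require(self.heading_frame in ("upwind", "wind"),
                 f"arena.heading_frame must be 'upwind' or 'wind', got {self.heading_frame!r}")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def wind_speed_mm(self) -> float:
        """Wind speed in mm/s."""
        return self.wind_speed * 1000.0

    @property
    def n_steps(self) -> int:
        return int(round(self.time_limit * self.sample_rate))

    def start_pose_global(self) -> tuple[float, float, float]:
        """Start pose with the heading expressed in the global (+x CCW) frame."""
        x, y, th = self.start_pose
        if self.heading_frame == "upwind":
            th = wrap_angle(math.pi + self.wind_angle + th)
        else:
            th = wrap_angle(th)
        return (x, y, th)

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.length_x and abs(y) <= self.width_y / 2.0


@dataclass
class PlumeConfig:
    """Parametric puff-plume process.

    Circular puffs are emitted at the source as a Poisson process, advected
    downwind, meander laterally as a Gaussian random walk, grow linearly and
    die after ``lifetime`` seconds.
    """

    emission_rate: float = 10.0       # puffs/s
    initial_radius: float = 10.0      # mm
    growth_rate: float = 12.0         # mm/s
    lifetime: float = 4.0             # s
    lateral_meander_sd: float = 30.0  # mm/sqrt(s)

    def __post_init__(self) -> None:
        _require(_finite(self.emission_rate, self.initial_radius,
                         self.growth_rate, self.lifetime, self.lateral_meander_sd),
                 "plume: non-finite value")
        _require(self.emission_rate >= 0, "plume.emission_rate must be >= 0")
        _require(self.initial_radius >= 0, "plume.initial_radius must be >= 0")
        _require(self.growth_rate >= 0, "plume.growth_rate must be >= 0")
        _require(self.lifetime > 0, "plume.lifetime must be > 0")
        _require(self.lateral_meander_sd >= 0, "plume.lateral_meander_sd must be >= 0")


@dataclass
class MothPolicyConfig:
    """Programmed-behaviour state machine parameters.

    After a (gated) odor hit the moth surges straight for ``surge_duration``,
    then zigzags (alternating-sign turning with forward motion) for
    ``zigzag_phase_duration``, then loops (constant-sign turning) until the
    next hit.  Before the first hit the moth does not move.  With probability
    ``deviation_rate`` per sample the commanded action is replaced by a pure
    rotation (v = 0) with |omega| drawn uniformly from the deviation bounds.
    """

    surge_duration: float = 0.5          # s; also the temporal-scheme threshold
    surge_speed: float = 24.0            # mm/s
    zigzag_speed: float = 12.0           # mm/s
    zigzag_turn_rate: float = 90.0       # deg/s
    zigzag_leg_duration: float = 2.0     # s
    zigzag_phase_duration: float = 6.0   # s of zigzag before the loop starts
    loop_speed: float = 12.0             # mm/s
    loop_turn_rate: float = 60.0         # deg/s
    deviation_rate: float = 0.0          # epsilon, probability per sample
    deviation_omega_min: float = 30.0    # deg/s
    deviation_omega_max: float = 180.0   # deg/s
    antenna_offset: float = 3.0          # mm, lateral offset of each antenna

    def __post_init__(self) -> None:
        _require(_finite(self.surge_duration, self.surge_speed, self.zigzag_speed,
                         self.zigzag_turn_rate, self.zigzag_leg_duration,
                         self.zigzag_phase_duration, self.loop_speed,
                         self.loop_turn_rate, self.deviation_rate,
                         self.deviation_omega_min, self.deviation_omega_max,
                         self.antenna_offset),
                 "policy: non-finite value")
        _require(0.0 <= self.deviation_rate <= 1.0,
                 "policy.deviation_rate must be in [0, 1]")
        _require(self.surge_duration > 0, "policy.surge_duration must be > 0")
        _require(self.zigzag_leg_duration > 0, "policy.zigzag_leg_duration must be > 0")
        _require(0 < self.deviation_omega_min <= self.deviation_omega_max,
                 "policy deviation omega bounds must satisfy 0 < min <= max")


@dataclass
class LikelihoodConfig:
    """Encounter-rate model and belief lattice used by the infotaxis observer.

    The mean rate at which an agent of radius ``agent_radius`` encounters odor
    particles emitted at rate ``emission_rate`` by a source, under advection
    at ``wind_speed`` with diffusivity ``diffusivity`` and particle lifetime
    ``particle_lifetime``, follows the classic two-dimensional closed form
    with correlation length lambda = sqrt(D*tau / (1 + V^2*tau/(4*D))).
    """

    emission_rate: float = 1.0       # R, expected hits/s at the source scale
    diffusivity: float = 2000.0      # D, mm^2/s
    particle_lifetime: float = 3.0   # tau, s
    wind_speed: float = 100.0        # V, mm/s
    wind_angle: float = 0.0          # rad
    agent_radius: float = 10.0       # a, mm (half the average body length)
    cell_size: float = 5.0           # belief lattice cell, mm

    def __post_init__(self) -> None:
        _require(_finite(self.emission_rate, self.diffusivity,
                         self.particle_lifetime, self.wind_speed,
                         self.wind_angle, self.agent_radius, self.cell_size),
                 "likelihood: non-finite value")
        for name in ("emission_rate", "diffusivity", "particle_lifetime",
                     "agent_radius", "cell_size"):
            _require(getattr(self, name) > 0, f"likelihood.{name} must be > 0")
        _require(self.wind_speed >= 0, "likelihood.wind_speed must be >= 0")
        _require(self.agent_radius < self.correlation_length,
                 "likelihood: agent_radius must be smaller than the correlation "
                 f"length lambda={self.correlation_length:.3f} mm for ln(lambda/a) > 0")

    @property
    def correlation_length(self) -> float:
        """lambda = sqrt(D*tau / (1 + V^2*tau/(4*D))) in mm."""
        d, tau, v = self.diffusivity, self.particle_lifetime, self.wind_speed
        return math.sqrt(d * tau / (1.0 + v * v * tau / (4.0 * d)))


@dataclass
class ClassifyConfig:
    """Thresholds of the temporal and kinematic maneuver schemes."""

    surge_blank_max: float = 0.5    # s, blank duration bound of the surge clauses
    rotate_blank_min: float = 0.2   # s, lower blank bound of the rotate clause
    slow_omega_max: float = 5.0     # deg/s, |omega| bound of the slow-surge clause
    min_speed: float = 0.0          # mm/s, dead-band on v > 0

    def __post_init__(self) -> None:
        _require(_finite(self.surge_blank_max, self.rotate_blank_min,
                         self.slow_omega_max, self.min_speed),
                 "classify: non-finite value")
        _require(self.surge_blank_max > 0, "classify.surge_blank_max must be > 0")
        _require(self.rotate_blank_min >= 0, "classify.rotate_blank_min must be >= 0")
        _require(self.slow_omega_max >= 0, "classify.slow_omega_max must be >= 0")
        _require(self.min_speed >= 0, "classify.min_speed must be >= 0")


@dataclass
class AnalysisConfig:
    """Reward-analysis parameters."""

    rmse_window: int = 20            # N samples per non-overlapping RMSE window
    hit_rate_window: float = 1.0     # s, trailing window for the hit rate
    hit_rate_edges: list[float] = field(default_factory=lambda: [0.0, 1.0, 2.0, 4.0, 8.0, 16.0])
    cum_hits_edges: list[float] = field(default_factory=lambda: [0.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0])
    histogram_bins: int = 50
    alpha: float = 0.05

    def __post_init__(self) -> None:
        _require(self.rmse_window >= 2, "analysis.rmse_window must be >= 2")
        _require(self.hit_rate_window > 0, "analysis.hit_rate_window must be > 0")
        _require(0.0 < self.alpha < 1.0, "analysis.alpha must be in (0, 1)")
        _require(self.histogram_bins >= 1, "analysis.histogram_bins must be >= 1")
        for name in ("hit_rate_edges", "cum_hits_edges"):
            edges = getattr(self, name)
            _require(len(edges) >= 2 and all(b > a for a, b in zip(edges, edges[1:])),
                     f"analysis.{name} must be strictly increasing with >= 2 edges")


_SECTIONS = {
    "arena": ArenaConfig,
    "plume": PlumeConfig,
    "policy": MothPolicyConfig,
    "likelihood": LikelihoodConfig,
    "classify": ClassifyConfig,
    "analysis": AnalysisConfig,
}


@dataclass
class PipelineConfig:
    """Bundle of all stage configurations (the content of one config file)."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    plume: PlumeConfig = field(default_factory=PlumeConfig)
    policy: MothPolicyConfig = field(default_factory=MothPolicyConfig)
    likelihood: LikelihoodConfig = field(default_factory=LikelihoodConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def _build_section(cls: type, name: str, data: Mapping[str, Any]):
    if not isinstance(data, Mapping):
        raise ConfigError(f"section '{name}' must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key '{sorted(unknown)[0]}' in section '{name}'")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            default = getattr(cls, key, None)
            if isinstance(default, tuple):
                value = tuple(value)
        kwargs[key] = value
    # tuple-typed fields arrive from YAML as lists
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(f.default, tuple):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path_or_mapping) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file (or a parsed mapping).

    Unknown sections or keys raise :class:`ConfigError` naming the offender.
    Missing sections or keys fall back to the defaults.
    """
    if isinstance(path_or_mapping, Mapping):
        data = dict(path_or_mapping)
    else:
        with open(path_or_mapping, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError("config file must contain a mapping of sections")
        data = dict(data)
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config section '{sorted(unknown)[0]}'")
    sections = {}
    for name, cls in _SECTIONS.items():
        sections[name] = _build_section(cls, name, data.get(name, {}) or {})
    return PipelineConfig(**sections)


def dump_config(cfg: PipelineConfig) -> str:
    """Serialize a configuration to canonical YAML."""
    payload = {name: dataclasses.asdict(getattr(cfg, name)) for name in _SECTIONS}
    return yaml.safe_dump(_jsonable(payload), sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, tuple):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, list):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def config_hash(cfg: PipelineConfig) -> str:
    """Stable sha256 hash of the full configuration."""
    payload = {name: _jsonable(dataclasses.asdict(getattr(cfg, name)))
               for name in _SECTIONS}
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
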