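"""Simulation configuration: every behavioural and environmental constant.

Shipped defaults are the study conditions: 100 adult-female agents, 120-day
season, 8-h nightly cycles of 28,800 one-second steps, 944 cavities in a
37-cell hexagonal habitat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["EnvironmentConfig", "BehaviourConfig", "SimulationConfig"]


@dataclass
class EnvironmentConfig:
    n_cavities: int = 944
    height_sd: float = 1.5          # m, within-cell spread of cavity heights
    plane_size: float = 9000.0      # m, side of the square flight plane
    count_profile: list[int] | None = None   # explicit per-cell counts
    height_means: list[float] | None = None  # explicit per-cell mean heights


@dataclass
class BehaviourConfig:
    v_min: float = 2.5      # m/s
    v_med: float = 3.7      # m/s
    v_max: float = 11.1     # m/s
    fop_angle: float = 270.0  # deg, field of perception
    fop_range: float = 150.0  # m
    max_turn_deg: float = 30.0  # per-step swerve bound
    qr_min: float = 30.0    # strict QR acceptance threshold
    gst_a: float = 10.0     # minimum group size
    gst_b: float = 100.0    # maximum group size
    w_ch: float = 0.5       # QR weight of cavity height
    w_le: float = 0.5       # QR weight of excrement load
    d_attr_min: float = 80.0   # m, attraction radius around signalled roost
    d_attr_max: float = 100.0
    pd_growth: float = 50.0    # m/day PD growth of the used roost
    pd_decay: float = 50.0     # m/day PD decay of unused roosts
    pd_max: float = 150.0      # m, PD ceiling
    night_exclusion_m: float = 0.0  # m, optional radius around failed-bout
    # roosts excluded from re-inspection for the rest of the night; 0
    # disables it (a group may keep advertising the same cavity until the
    # declining threshold lets it settle)
    home_radius_m: float = 150.0  # m, searchers farther than this from their
    # most recent roost first home back to its neighbourhood (site fidelity)
    max_failures_per_night: int = 15  # after this many failed bouts the
    # local cavity supply is exhausted and the agent roams freely instead
    # of homing, which lets chronic stragglers reach other swarms
    dawn_viability_min: float = 5.0  # bats; a swarm smaller than this at
    # the sunrise margin has not found a roost and disperses to fall back,
    # while any larger gathering enters and roosts as a group
    fallback_radius_m: float = 150.0  # m, an unsuccessful bat joins its
    # group-mates at dawn if they settled within this distance of its day
    # roost; otherwise it roosts alone at the day roost itself
    give_up_s: float = 0.0  # s into the cycle at which a still-unroosted
    # prospector abandons prospecting and returns to a remembered
    # neighbourhood to rejoin its lineage; 0 disables the rule
    prospect_exclusion_m: float = 300.0  # m, a prospecting bat ignores
    # roosts this close to the site it is dispersing from, so prospecting
    # reliably samples other neighbourhoods
    prospect_rate: float = 0.3  # nightly probability that a bat forgoes
    # its familiar neighbourhood and prospects across the roosting area,
    # the individual-level group switching of fission-fusion societies
    receiver_rate: float = 0.08  # per-second probability that a searcher
    # inside a signalled roost's attraction circle is recruited by it; the
    # complement passes by, so even a large swarm lets some bats through
    explore_rate: float = 0.015  # per-second probability of inspecting an
    # un-signalled empty cavity; keeps recruitment to advertised or occupied
    # roosts the far more likely choice and searchers receptive in between
    forage_min_s: float = 7200.0   # 2 h
    forage_max_s: float = 10800.0  # 3 h


@dataclass
class SimulationConfig:
    n_agents: int = 100
    n_days: int = 120
    cycle_s: int = 28800          # 8-h night at 1 s per step
    step_s: int = 1
    o_s: int = 10800              # midnight (cycle starts at 21:00)
    record_after_s: int = 25200   # 4:00, daily snapshot opens
    sunrise_margin_s: int = 300   # < 5 min to sunrise: forced housing
    daytime_s: int = 57600        # 16-h roosting block between cycles
    seed: int = 0
    track_transitions: bool = False
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    behaviour: BehaviourConfig = field(default_factory=BehaviourConfig)

    def __post_init__(self) -> None:
        if self.cycle_s % self.step_s:
            raise ValueError("step_s must divide cycle_s")
        if not self.o_s < self.record_after_s < self.cycle_s:
            raise ValueError("require o_s < record_after_s < cycle_s")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.behaviour.forage_max_s >= self.cycle_s - self.sunrise_margin_s:
            raise ValueError("foraging window must end before the sunrise margin")

    @property
    def steps_per_cycle(self) -> int:
        return self.cycle_s // self.step_s

    @property
    def steps_per_season(self) -> int:
        return self.steps_per_cycle * self.n_days

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        env = data.pop("environment", {}) or {}
        beh = data.pop("behaviour", {}) or {}
        return cls(
            environment=EnvironmentConfig(**env),
            behaviour=BehaviourConfig(**beh),
            **data,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
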