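"""One agent's kinematics, perception, roost evaluation and memory.

Agents fly a highly correlated random walk (small per-step swerve, 1 s steps)
with flight speeds drawn from a right-skewed distribution spanning
2.5-11.1 m/s (median 3.7 m/s).  They detect cavities within a 270 degree /
150 m field of perception (FoP), eavesdrop on swarming conspecifics within a
roost's 80-100 m attraction radius, judge cavities by the QR score and a
memory-based penalization distance (PD), and time their swarming bouts by the
t_attr / te_attr rules.  Group formation succeeds when occupancy reaches the
time-decaying group-size threshold (GST).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from enum import IntEnum

import numpy as np
from scipy.stats import gamma as gamma_dist

from .environment import Cavity, CavityField, QualityWeights, roost_quality

__all__ = [
    "Mode",
    "MemoryEntry",
    "AgentState",
    "FlightParams",
    "ThresholdParams",
    "sample_speeds",
    "displace",
    "reflect_into_plane",
    "step_movement",
    "perceive_cavities",
    "perception_mask",
    "perceive_signallers",
    "evaluate_roost",
    "memory_permits",
    "signalling_time",
    "signalling_extension",
    "group_size_threshold",
    "update_memory",
    "LEGAL_TRANSITIONS",
]


class Mode(IntEnum):
    """Behavioural modes of the agent state machine."""

    IN_ROOST = 0
    SIGNALLING = 1
    SEARCHING = 2
    FLYING_TO = 3
    FORAGING = 4


#: legal edges of the behavioural state machine.  Any mode may jump to
#: FLYING_TO via the sunrise rule; FLYING_TO may enter the roost directly
#: (sunrise entry / end-of-cycle housing) or begin a swarming bout.
LEGAL_TRANSITIONS: frozenset[tuple[int, int]] = frozenset(
    {
        (Mode.IN_ROOST, Mode.FORAGING),   # evening emergence
        (Mode.FORAGING, Mode.SEARCHING),  # foraging window over
        (Mode.SEARCHING, Mode.FLYING_TO),  # cavity or signalled roost chosen
        (Mode.FLYING_TO, Mode.SIGNALLING),  # arrival at accepted cavity
        (Mode.SIGNALLING, Mode.IN_ROOST),  # bout elapsed, enter roost
        (Mode.IN_ROOST, Mode.SEARCHING),  # group dissolution below GST
        (Mode.SEARCHING, Mode.FLYING_TO),
        (Mode.FORAGING, Mode.FLYING_TO),  # sunrise rule
        (Mode.SEARCHING, Mode.FLYING_TO),
        (Mode.SIGNALLING, Mode.FLYING_TO),
        (Mode.IN_ROOST, Mode.FLYING_TO),
        (Mode.FLYING_TO, Mode.IN_ROOST),  # sunrise entry / housing
    }
)


@dataclass
class MemoryEntry:
    """Penalization record for one formerly used roost."""

    roost_id: int
    penalization_distance: float  # PD, m, in [0, 150]
    last_used_day: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.penalization_distance <= 150.0:
            raise ValueError("PD must lie in [0, 150] m")


@dataclass
class AgentState:
    """A bat's kinematic state, behavioural mode, timers and roost memory."""

    id: int
    position: tuple[float, float]
    heading: float
    mode: Mode = Mode.IN_ROOST
    current_roost: int | None = None
    target_roost: int | None = None
    foraging_end: float = 0.0
    signalling_deadline: float = 0.0
    memory: list[MemoryEntry] = dc_field(default_factory=list)


@dataclass
class FlightParams:
    """Species flight envelope and perception geometry."""

    v_min: float = 2.5   # m/s, take-off velocity of similar-sized species
    v_med: float = 3.7   # m/s, median commuting speed
    v_max: float = 11.1  # m/s
    fop_angle: float = 270.0  # degrees, forward perception sector
    fop_range: float = 150.0  # m
    max_turn: float = math.radians(30.0)  # per-step swerve bound
    speed_shape: float = 2.0  # gamma shape of the speed distribution

    def __post_init__(self) -> None:
        if not self.v_min <= self.v_med <= self.v_max:
            raise ValueError("require v_min <= v_med <= v_max")
        if not 0.0 < self.fop_angle <= 360.0:
            raise ValueError("fop_angle must lie in (0, 360]")
        if self.fop_range <= 0:
            raise ValueError("fop_range must be > 0")
        # scale of the shifted gamma solved so its median is v_med; the
        # clipped mass above v_max is ~1e-4 and does not move the median
        self.speed_scale = (self.v_med - self.v_min) / gamma_dist.ppf(
            0.5, self.speed_shape
        )


def sample_speeds(
    rng: np.random.Generator, n: int, params: FlightParams
) -> np.ndarray:
    """Right-skewed flight speeds on [v_min, v_max] with median v_med."""
    s = params.v_min + rng.gamma(params.speed_shape, params.speed_scale, size=n)
    return np.clip(s, params.v_min, params.v_max)


def displace(
    position: np.ndarray,
    heading: np.ndarray,
    speed: np.ndarray,
    swerve: np.ndarray,
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic movement core: new_pos = pos + v_d + v_s.

    The directed component v_d travels at ``speed`` along the swerved
    heading; ``swerve`` is the bounded per-step heading change that keeps the
    walk highly correlated (nearly linear paths).
    """
    heading = np.asarray(heading, dtype=float) + np.asarray(swerve, dtype=float)
    step = np.asarray(speed, dtype=float) * dt
    delta = np.stack([step * np.cos(heading), step * np.sin(heading)], axis=-1)
    return np.asarray(position, dtype=float) + delta, heading


def reflect_into_plane(
    position: np.ndarray, heading: np.ndarray, plane_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Reflect positions (and headings) at the plane boundary."""
    pos = np.array(position, dtype=float, copy=True)
    heading = np.array(heading, dtype=float, copy=True)
    for axis in (0, 1):
        coord = pos[..., axis]
        low = coord < 0
        high = coord > plane_size
        if np.any(low) or np.any(high):
            coord[low] = -coord[low]
            coord[high] = 2 * plane_size - coord[high]
            flipped = low | high
            if axis == 0:
                heading[flipped] = np.pi - heading[flipped]
            else:
                heading[flipped] = -heading[flipped]
            pos[..., axis] = np.clip(coord, 0.0, plane_size)
    return pos, heading


def step_movement(
    agent: AgentState,
    params: FlightParams,
    dt: float,
    rng: np.random.Generator,
    plane_size: float = 9000.0,
) -> AgentState:
    """Advance one flying agent by one step of the correlated random walk."""
    if agent.mode not in (Mode.SEARCHING, Mode.FLYING_TO, Mode.FORAGING):
        raise ValueError("step_movement requires a flying mode (2, 3 or 4)")
    swerve = rng.uniform(-params.max_turn, params.max_turn)
    speed = sample_speeds(rng, 1, params)[0]
    pos, heading = displace(
        np.array(agent.position)[None, :], np.array([agent.heading]), speed,
        swerve, dt,
    )
    pos, heading = reflect_into_plane(pos, heading, plane_size)
    agent.position = (float(pos[0, 0]), float(pos[0, 1]))
    agent.heading = float(heading[0] % (2 * np.pi))
    return agent


def perception_mask(
    position: np.ndarray,
    heading: float,
    points: np.ndarray,
    params: FlightParams,
) -> np.ndarray:
    """Boolean mask of ``points`` inside the forward FoP sector.

    A point is perceived iff its distance is <= fop_range and its bearing
    relative to the heading falls within the forward sector (the complement
    is the blind cone behind the agent).  A point at zero distance is
    perceived.
    """
    d = points - np.asarray(position, dtype=float)
    dist = np.hypot(d[:, 0], d[:, 1])
    bearing = np.arctan2(d[:, 1], d[:, 0]) - heading
    bearing = (bearing + np.pi) % (2 * np.pi) - np.pi
    half = math.radians(params.fop_angle) / 2.0
    return (dist <= params.fop_range) & ((np.abs(bearing) <= half) | (dist == 0.0))


def perceive_cavities(
    agent: AgentState, field: CavityField, params: FlightParams
) -> np.ndarray:
    """Indices of field cavities inside the agent's field of perception."""
    mask = perception_mask(
        np.array(agent.position), agent.heading, field.xy, params
    )
    return np.flatnonzero(mask)


def perceive_signallers(
    position: np.ndarray,
    roost_ids: np.ndarray,
    roost_xy: np.ndarray,
    radii: np.ndarray,
    n_signallers: np.ndarray,
) -> int | None:
    """Pick the signalled roost recruiting a searching agent at ``position``.

    Among roosts whose attraction circle contains the agent and which have at
    least one signaller, returns the id of the roost with the most
    signallers; ties break by distance, then by lowest id.  None if no roost
    recruits.
    """
    roost_xy = np.asarray(roost_xy, dtype=float).reshape(-1, 2)
    d = np.hypot(*(roost_xy - np.asarray(position, dtype=float)).T)
    ok = (d <= np.asarray(radii, dtype=float)) & (np.asarray(n_signallers) >= 1)
    if not np.any(ok):
        return None
    idx = np.flatnonzero(ok)
    order = np.lexsort(
        (np.asarray(roost_ids)[idx], d[idx], -np.asarray(n_signallers)[idx])
    )
    return int(np.asarray(roost_ids)[idx[order[0]]])


def memory_permits(
    cavity_xy: np.ndarray,
    penalized_xy: np.ndarray,
    penalization_distances: np.ndarray,
) -> bool:
    """True iff the cavity clears every penalized roost's exclusion radius."""
    penalized_xy = np.asarray(penalized_xy, dtype=float).reshape(-1, 2)
    if len(penalized_xy) == 0:
        return True
    d = np.hypot(*(penalized_xy - np.asarray(cavity_xy, dtype=float)).T)
    return bool(np.all(d > np.asarray(penalization_distances, dtype=float)))


def evaluate_roost(
    cavity: Cavity,
    max_height: float,
    weights: QualityWeights,
    qr_min: float,
    penalized_xy: np.ndarray,
    penalization_distances: np.ndarray,
) -> bool:
    """Accept an un-signalled cavity iff QR exceeds the threshold (strict)
    and it lies beyond the PD radius of every remembered roost."""
    qr = roost_quality(cavity, max_height, weights)
    if qr <= qr_min:
        return False
    return memory_permits(
        np.array([cavity.x, cavity.y]), penalized_xy, penalization_distances
    )


def signalling_time(cavity: Cavity, t: float, sunrise: float) -> float:
    """Base swarming-bout duration t_attr = (CH^2 + 1) + NRB + 1000/TTS.

    Tall cavities are advertised longer, occupants extend the bout, and the
    effort term grows as time-to-sunrise (TTS) runs out.
    """
    tts = sunrise - t
    if tts <= 0:
        raise ValueError("signalling requires time before sunrise (TTS > 0)")
    return (cavity.height**2 + 1.0) + cavity.n_roosting + 1000.0 / tts


def signalling_extension(cavity: Cavity) -> float:
    """Extension te_attr = NSB^2 / 2 driven by co-swarming bats."""
    if cavity.n_signalling < 0:
        raise ValueError("NSB must be >= 0")
    return cavity.n_signalling**2 / 2.0


@dataclass
class ThresholdParams:
    """Parameters of the time-decaying group-size threshold (GST)."""

    a: float = 10.0       # minimum group size
    b: float = 100.0      # maximum group size
    o: float = 10800.0    # s into cycle when effort decay starts (midnight)
    t_sim: float = 28800.0  # cycle length, s
    qr_min: float = 30.0  # QR acceptance threshold (strict >)

    def __post_init__(self) -> None:
        if not 0 < self.a <= self.b:
            raise ValueError("require 0 < a <= b")
        if not 0 <= self.o < self.t_sim:
            raise ValueError("require 0 <= o < t_sim")


def group_size_threshold(t: float, params: ThresholdParams) -> float:
    """Group size at which a swarming bout counts as successful.

    GST stays at b until time o (midnight), then decays as
    b - (b - a)(t - o)/(t_sim - t); the value is clamped to [a, b] because
    the decay branch diverges as t approaches the end of the cycle and a
    group below the stated minimum is meaningless.
    """
    if not 0 <= t <= params.t_sim:
        raise ValueError("t must lie within [0, t_sim]")
    if t <= params.o:
        return params.b
    if t == params.t_sim:
        return params.a
    gst = params.b - (params.b - params.a) * (t - params.o) / (params.t_sim - t)
    return float(min(params.b, max(params.a, gst)))


def update_memory(
    memory: list[MemoryEntry],
    current_roost: int | None,
    day: int,
    growth: float = 50.0,
    decay: float = 50.0,
    pd_max: float = 150.0,
) -> list[MemoryEntry]:
    """End-of-day PD update: grow the used roost's radius, shrink the rest.

    The roost used today gains ``growth`` metres of exclusion radius (capped
    at ``pd_max``); every other remembered roost loses ``decay`` metres and
    is forgotten at zero.  Returns the new memory list.
    """
    out: list[MemoryEntry] = []
    seen = False
    for entry in memory:
        if current_roost is not None and entry.roost_id == current_roost:
            pd = min(pd_max, entry.penalization_distance + growth)
            out.append(MemoryEntry(entry.roost_id, pd, day))
            seen = True
        else:
            pd = entry.penalization_distance - decay
            if pd > 0:
                out.append(MemoryEntry(entry.roost_id, pd, entry.last_used_day))
    if current_roost is not None and not seen:
        out.append(MemoryEntry(current_roost, min(pd_max, growth), day))
    return out
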