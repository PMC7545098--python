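"""Season orchestration: the shared clock, nightly cycles and daily records.

A season is a sequence of nightly cycles (t = 0 at the 21:00 evening
emergence, sunrise at t = cycle_s).  Each cycle runs emergence, individual
foraging windows, searching/swarming, and forced housing in the final five
minutes.  The daily output snapshot is the set of occupied cavities with
group sizes, taken at the first step after 4:00 at which every agent is
housed; the 16-h daytime block between cycles is applied as a single bulk
update of excrement loads and roost memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import behaviour as bhv
from .behaviour import Mode, MemoryEntry, FlightParams, ThresholdParams
from .config import SimulationConfig
from .environment import (
    CavityField,
    HexGrid,
    QualityWeights,
    build_hex_grid,
    daytime_excrement_update,
    generate_synthetic_environment,
    roost_quality_field,
)

__all__ = [
    "DailyRoostRecord",
    "SimulationResult",
    "EngineState",
    "initialize_season",
    "run_cycle",
    "run_season",
    "run_replicates",
    "switching_distances",
]

RECORD_COLUMNS = [
    "day",
    "cavity_id",
    "group_size",
    "roost_height",
    "x",
    "y",
    "is_maximum_group",
]


@dataclass
class DailyRoostRecord:
    """One occupied cavity with its group size at the daily snapshot."""

    day: int
    cavity_id: int
    group_size: int
    roost_height: float
    x: float
    y: float
    is_maximum_group: bool


@dataclass
class SimulationResult:
    """Records of one replicate plus everything needed to replay it."""

    records: pd.DataFrame
    config: SimulationConfig
    seed: int
    replicate: int = 0
    transitions: list | None = None


class EngineState:
    """Mutable per-season state: agent arrays, cavity occupancy, clock."""

    def __init__(
        self, config: SimulationConfig, field: CavityField, rng: np.random.Generator
    ) -> None:
        if len(field) == 0:
            raise ValueError("cavity field is empty")
        self.config = config
        self.field = field
        self.rng = rng
        b = config.behaviour
        self.flight = FlightParams(
            v_min=b.v_min,
            v_med=b.v_med,
            v_max=b.v_max,
            fop_angle=b.fop_angle,
            fop_range=b.fop_range,
            max_turn=np.deg2rad(b.max_turn_deg),
        )
        self.thresholds = ThresholdParams(
            a=b.gst_a, b=b.gst_b, o=config.o_s, t_sim=config.cycle_s, qr_min=b.qr_min
        )
        self.weights = QualityWeights(b.w_ch, b.w_le)

        n = config.n_agents
        start = int(rng.integers(len(field)))
        self.pos = np.tile(field.xy[start], (n, 1))
        self.heading = np.zeros(n)
        self.mode = np.full(n, int(Mode.IN_ROOST), dtype=np.int8)
        self.current_roost = np.full(n, start, dtype=np.int64)
        self.last_roost = np.full(n, start, dtype=np.int64)
        # where the bat last spent a day; the sunrise fallback returns here,
        # not to cavities briefly entered during failed nocturnal bouts
        self.day_roost = np.full(n, start, dtype=np.int64)
        self.target = np.full(n, -1, dtype=np.int64)
        self.timer = np.zeros(n)
        self.memory: list[list[MemoryEntry]] = [[] for _ in range(n)]
        field.reset_occupancy()
        field.n_roosting[start] = n

        self.day = 0
        self.tree = cKDTree(field.xy)
        pad = self.flight.fop_range
        self.bbox = (
            field.xy[:, 0].min() - pad,
            field.xy[:, 1].min() - pad,
            field.xy[:, 0].max() + pad,
            field.xy[:, 1].max() + pad,
        )
        self.transitions: list[tuple[int, int, int, int, int]] = []
        # roosts abandoned after failed bouts tonight (indices), per agent
        self.night_excl: list[list[int]] = [[] for _ in range(n)]
        self.fail_count = np.zeros(n, dtype=np.int64)
        # per-night homing anchor: a remembered roost whose neighbourhood
        # the agent returns to after foraging
        self.anchor = self.last_roost.copy()
        # per-cycle caches, filled by run_cycle
        self._qr = np.zeros(len(field))
        self._pen_xy: list[np.ndarray] = [np.empty((0, 2)) for _ in range(n)]
        self._pen_pd: list[np.ndarray] = [np.empty(0) for _ in range(n)]

    # -- state-machine bookkeeping -------------------------------------

    def _set_mode(self, i: int, new: Mode, t: int) -> None:
        old = Mode(self.mode[i])
        if old == new:
            return
        if self.config.track_transitions:
            if (old, new) not in bhv.LEGAL_TRANSITIONS:
                raise RuntimeError(
                    f"illegal transition {old.name} -> {new.name} "
                    f"(agent {i}, day {self.day}, t={t})"
                )
            self.transitions.append((self.day, t, i, int(old), int(new)))
        self.mode[i] = int(new)

    def _enter_roost(self, i: int, roost: int, t: int) -> None:
        self._set_mode(i, Mode.IN_ROOST, t)
        self.current_roost[i] = roost
        self.last_roost[i] = roost
        self.target[i] = -1
        self.pos[i] = self.field.xy[roost]
        self.field.n_roosting[roost] += 1

    def _dissolve_if_below_threshold(self, roost: int, t: int) -> None:
        """Check a roost when its last signaller has entered (NSB hit 0)."""
        gst = bhv.group_size_threshold(t, self.thresholds)
        nrb = int(self.field.n_roosting[roost])
        if nrb >= gst or nrb == 0:
            return
        members = np.flatnonzero(
            (self.mode == int(Mode.IN_ROOST)) & (self.current_roost == roost)
        )
        radius = float(self.field.attraction_radius[roost])
        for i in members:
            self._set_mode(int(i), Mode.SEARCHING, t)
            self.current_roost[i] = -1
            # the dispersing bats resume searching from within the swarming
            # annulus around the abandoned roost, not from its entrance
            ang = self.rng.uniform(0.0, 2 * np.pi)
            r = radius * np.sqrt(self.rng.uniform())
            self.pos[i] = self.field.xy[roost] + [
                r * np.cos(ang), r * np.sin(ang)
            ]
            self.heading[i] = self.rng.uniform(0.0, 2 * np.pi)
            self.night_excl[int(i)].append(roost)
            self.fail_count[i] += 1
        self.field.n_roosting[roost] = 0

    def _dawn_fallback(self, i: int) -> int:
        """Where an unsuccessful bat goes at dawn: its group's roost.

        The bat returns to its most recent day roost; if its former
        group-mates have settled nearby (within fallback_radius), it joins
        them there instead of roosting alone at the abandoned cavity.
        """
        home = int(self.day_roost[i])
        radius = self.config.behaviour.fallback_radius_m
        occupied = np.flatnonzero(self.field.n_roosting > 0)
        if len(occupied) == 0 or radius <= 0:
            return home
        d = np.hypot(*(self.field.xy[occupied] - self.field.xy[home]).T)
        j = int(np.argmin(d))
        return int(occupied[j]) if d[j] <= radius else home

    def _begin_signalling(self, i: int, roost: int, t: int) -> None:
        fld = self.field
        if fld.n_signalling[roost] == 0:
            # one attraction radius per swarming bout at this roost
            b = self.config.behaviour
            fld.attraction_radius[roost] = self.rng.uniform(b.d_attr_min, b.d_attr_max)
        fld.n_signalling[roost] += 1
        self._set_mode(i, Mode.SIGNALLING, t)
        t_attr = (fld.height[roost] ** 2 + 1.0) + fld.n_roosting[roost] + 1000.0 / (
            self.config.cycle_s - t
        )
        # base deadline; the live te_attr extension (NSB^2/2) is added on top
        self.timer[i] = t + t_attr


def initialize_season(
    config: SimulationConfig, field: CavityField, rng: np.random.Generator
) -> EngineState:
    """Place all agents in one uniformly chosen roost, clock at day 0, t = 0."""
    return EngineState(config, field, rng)


def _emerge(state: EngineState) -> None:
    """Evening emergence: everyone leaves the roost and starts foraging."""
    cfg = state.config
    n = cfg.n_agents
    rng = state.rng
    state.pos = state.field.xy[state.current_roost].copy()
    state.heading = rng.uniform(0.0, 2 * np.pi, n)
    b = cfg.behaviour
    state.timer = rng.uniform(b.forage_min_s, b.forage_max_s, n)
    for i in range(n):
        state._set_mode(i, Mode.FORAGING, 0)
    state.current_roost[:] = -1
    state.target[:] = -1
    state.night_excl = [[] for _ in range(n)]
    state.fail_count[:] = 0
    # tonight's familiar neighbourhood is where the bat spent the day;
    # a prospecting minority forgoes it and samples the habitat at large
    prospecting = rng.random(n) < b.prospect_rate
    state.anchor[:] = np.where(prospecting, -1, state.day_roost)
    state.field.reset_occupancy()
    # QR and memory exclusion zones are fixed for the night
    state._qr = roost_quality_field(state.field, state.weights)
    for i in range(n):
        mem = state.memory[i]
        if mem:
            idx = np.array([m.roost_id for m in mem], dtype=np.int64)
            state._pen_xy[i] = state.field.xy[idx]
            state._pen_pd[i] = np.array([m.penalization_distance for m in mem])
        else:
            state._pen_xy[i] = np.empty((0, 2))
            state._pen_pd[i] = np.empty(0)


def _filter_acceptable(
    state: EngineState, ai: int, cands: np.ndarray, night_excl: bool = True
) -> np.ndarray:
    """Apply the un-signalled-cavity acceptance rules for one agent."""
    fld = state.field
    night_r = state.config.behaviour.night_exclusion_m
    excl = state.night_excl[ai] if night_excl and night_r > 0 else []
    if excl:
        # predation-risk avoidance: no re-inspection near roosts whose
        # bout failed tonight
        d_ex = np.hypot(
            fld.xy[cands][:, None, 0] - fld.xy[excl][None, :, 0],
            fld.xy[cands][:, None, 1] - fld.xy[excl][None, :, 1],
        )
        cands = cands[(d_ex > night_r).all(axis=1)]
    cands = cands[state._qr[cands] > state.thresholds.qr_min]
    keep = [
        int(c)
        for c in cands
        if bhv.memory_permits(fld.xy[c], state._pen_xy[ai], state._pen_pd[ai])
    ]
    return np.asarray(keep, dtype=np.int64)


def _searching_decisions(state: EngineState, searchers: np.ndarray, t: int) -> None:
    """Receiver-first roost selection for agents in SEARCHING mode.

    Only searchers inside the habitat's padded bounding box can act: every
    cavity is at least fop_range away from agents outside it, which exceeds
    any attraction radius.  The cheap stochastic gates (probabilistic
    recruitment, rare exploration) run first so the geometric work touches
    only the handful of agents acting this second.
    """
    fld = state.field
    rng = state.rng
    b = state.config.behaviour
    x0, y0, x1, y1 = state.bbox
    px, py = state.pos[searchers, 0], state.pos[searchers, 1]
    searchers = searchers[(px >= x0) & (px <= x1) & (py >= y0) & (py <= y1)]
    if not len(searchers):
        return

    recruited: set[int] = set()
    # active swarms recruit within their attraction circle; occupied roosts
    # keep attracting the same way (calls from roosting bats carry on into
    # dawn), which lets late stragglers join groups that already settled
    sig = np.flatnonzero((fld.n_signalling > 0) | (fld.n_roosting > 0))
    if len(sig):
        # recruitment by a passing swarm is probabilistic, not certain
        gate = rng.random(len(searchers)) < b.receiver_rate
        sub = searchers[gate]
        if len(sub):
            diff = state.pos[sub][:, None, :] - fld.xy[sig][None, :, :]
            dist = np.hypot(diff[..., 0], diff[..., 1])
            within = dist <= fld.attraction_radius[sig][None, :]
            # prospectors are dispersing: roosts near their natal site do
            # not recruit them
            prospecting = state.anchor[sub] < 0
            if prospecting.any() and b.prospect_exclusion_m > 0:
                natal = fld.xy[state.last_roost[sub]]
                d_natal = np.hypot(
                    fld.xy[sig][None, :, 0] - natal[:, None, 0],
                    fld.xy[sig][None, :, 1] - natal[:, None, 1],
                )
                within &= ~(prospecting[:, None] & (d_natal <= b.prospect_exclusion_m))
            nsb = fld.n_signalling[sig]
            for row in np.flatnonzero(within.any(axis=1)):
                ai = int(sub[row])
                cols = np.flatnonzero(within[row])
                order = np.lexsort((sig[cols], dist[row, cols], -nsb[cols]))
                choice = int(sig[cols[order[0]]])
                state._set_mode(ai, Mode.FLYING_TO, t)
                state.target[ai] = choice
                recruited.add(ai)

    # explorers: evaluate un-signalled cavities within the FoP.  An agent
    # only engages when an occupied roost could be in perception range or
    # its rare exploration impulse fires.
    rest = np.array(
        [int(ai) for ai in searchers if int(ai) not in recruited], dtype=np.int64
    )
    if not len(rest):
        return
    explore_draw = rng.random(len(rest)) < b.explore_rate
    occ_idx = np.flatnonzero((fld.n_roosting > 0) & (fld.n_signalling == 0))
    if len(occ_idx):
        d_occ = np.hypot(
            state.pos[rest][:, None, 0] - fld.xy[occ_idx][None, :, 0],
            state.pos[rest][:, None, 1] - fld.xy[occ_idx][None, :, 1],
        )
        near_occ = (d_occ <= state.flight.fop_range).any(axis=1)
    else:
        near_occ = np.zeros(len(rest), dtype=bool)
    active = explore_draw | near_occ
    if not active.any():
        return
    rest = rest[active]
    explore_draw = explore_draw[active]
    pex = b.prospect_exclusion_m
    cand_lists = state.tree.query_ball_point(
        state.pos[rest], state.flight.fop_range
    )
    for ai, may_explore, cands in zip(rest, explore_draw, cand_lists):
        ai = int(ai)
        if not cands:
            continue
        cands = np.asarray(cands, dtype=np.int64)
        if state.anchor[ai] < 0 and pex > 0:
            natal_xy = fld.xy[state.last_roost[ai]]
            d_natal = np.hypot(*(fld.xy[cands] - natal_xy).T)
            cands = cands[d_natal > pex]
            if len(cands) == 0:
                continue
        # an occupied roost is always worth inspecting once perceived; an
        # empty cavity only occasionally, so recruitment to advertised or
        # occupied roosts stays the far more likely choice and searchers
        # remain receptive between inspections
        occupied = cands[
            (fld.n_roosting[cands] > 0) & (fld.n_signalling[cands] == 0)
        ]
        pick = -1
        if len(occupied):
            occupied = occupied[
                bhv.perception_mask(
                    state.pos[ai], state.heading[ai], fld.xy[occupied],
                    state.flight,
                )
            ]
            # joining an established group is quiet entry, not fresh
            # advertising: tonight's failed-bout exclusions do not apply
            occupied = _filter_acceptable(state, ai, occupied, night_excl=False)
            if len(occupied):
                d = np.hypot(*(fld.xy[occupied] - state.pos[ai]).T)
                pick = int(occupied[np.argmin(d)])
        if pick < 0:
            if not may_explore:
                continue
            mask = bhv.perception_mask(
                state.pos[ai], state.heading[ai], fld.xy[cands], state.flight
            )
            empty = cands[
                mask
                & (fld.n_signalling[cands] == 0)
                & (fld.n_roosting[cands] == 0)
            ]
            empty = _filter_acceptable(state, ai, empty)
            if not len(empty):
                continue
            # inspect the nearest acceptable cavity first
            d = np.hypot(*(fld.xy[empty] - state.pos[ai]).T)
            pick = int(empty[np.argmin(d)])
        state._set_mode(ai, Mode.FLYING_TO, t)
        state.target[ai] = pick


def _snapshot(state: EngineState) -> list[DailyRoostRecord]:
    fld = state.field
    occupied = np.flatnonzero(fld.n_roosting > 0)
    total = int(fld.n_roosting[occupied].sum())
    if total != state.config.n_agents:
        raise RuntimeError(
            f"day {state.day}: snapshot group sizes sum to {total}, "
            f"expected {state.config.n_agents}"
        )
    # maximum-group flag: largest group, ties to the lowest cavity id
    order = np.lexsort((fld.ids[occupied], -fld.n_roosting[occupied]))
    max_pos = occupied[order[0]]
    return [
        DailyRoostRecord(
            day=state.day,
            cavity_id=int(fld.ids[i]),
            group_size=int(fld.n_roosting[i]),
            roost_height=float(fld.height[i]),
            x=float(fld.xy[i, 0]),
            y=float(fld.xy[i, 1]),
            is_maximum_group=bool(i == max_pos),
        )
        for i in occupied
    ]


def run_cycle(state: EngineState) -> list[DailyRoostRecord]:
    """Run one 8-h nightly cycle and return the day's roost records."""
    cfg = state.config
    fld = state.field
    rng = state.rng
    fp = state.flight
    cycle = cfg.cycle_s
    margin_t = cycle - cfg.sunrise_margin_s
    sunrise_phase = False
    records: list[DailyRoostRecord] | None = None

    _emerge(state)

    t = 0
    while t < cycle:
        t += cfg.step_s

        # sunrise rule: < 5 min left, every agent must secure a roost.
        # A swarm too small to ever reach the threshold has not "found" a
        # roost: its bats return to where they last spent a day.  Viable
        # swarms enter their cavity.
        if not sunrise_phase and t >= margin_t:
            sunrise_phase = True
            viable = np.zeros(len(fld), dtype=bool)
            signalled = np.flatnonzero(fld.n_signalling > 0)
            viable[signalled] = (
                fld.n_signalling[signalled] + fld.n_roosting[signalled]
                >= cfg.behaviour.dawn_viability_min
            )
            for i in np.flatnonzero(state.mode == int(Mode.SIGNALLING)):
                i = int(i)
                roost = int(state.target[i])
                fld.n_signalling[roost] -= 1
                if viable[roost]:
                    state._enter_roost(i, roost, t)
                else:
                    state._set_mode(i, Mode.FLYING_TO, t)
                    state.target[i] = state._dawn_fallback(i)
            # occupants of abandoned non-viable swarms disperse likewise
            for roost in signalled[~viable[signalled]]:
                roost = int(roost)
                members = np.flatnonzero(
                    (state.mode == int(Mode.IN_ROOST))
                    & (state.current_roost == roost)
                )
                for i in members:
                    i = int(i)
                    state._set_mode(i, Mode.FLYING_TO, t)
                    state.current_roost[i] = -1
                    state.target[i] = state._dawn_fallback(i)
                fld.n_roosting[roost] = 0
            for i in np.flatnonzero(
                (state.mode == int(Mode.SEARCHING))
                | (state.mode == int(Mode.FORAGING))
            ):
                i = int(i)
                state._set_mode(i, Mode.FLYING_TO, t)
                state.target[i] = state._dawn_fallback(i)
            # in-flight agents keep only targets worth keeping
            for i in np.flatnonzero(state.mode == int(Mode.FLYING_TO)):
                i = int(i)
                tgt = int(state.target[i])
                if not (viable[tgt] or fld.n_roosting[tgt] > 0):
                    state.target[i] = state._dawn_fallback(i)

        # late in the night, bats that have not yet settled anywhere give
        # up prospecting/roaming and fall back to a remembered
        # neighbourhood, where they can join an established group
        if cfg.behaviour.give_up_s and t == int(cfg.behaviour.give_up_s):
            for i in np.flatnonzero(state.mode == int(Mode.SEARCHING)):
                i = int(i)
                known = [m.roost_id for m in state.memory[i]]
                if int(state.last_roost[i]) not in known:
                    known.append(int(state.last_roost[i]))
                state.anchor[i] = known[rng.integers(len(known))]
                state.fail_count[i] = 0

        # correlated random walk for searchers and foragers; a searcher far
        # from its most recent roost first homes back to that neighbourhood
        # (site fidelity), then searches locally
        rw = np.flatnonzero(
            (state.mode == int(Mode.SEARCHING)) | (state.mode == int(Mode.FORAGING))
        )
        if len(rw):
            searching = state.mode[rw] == int(Mode.SEARCHING)
            loyal = (
                searching
                & (state.anchor[rw] >= 0)
                & (state.fail_count[rw] < cfg.behaviour.max_failures_per_night)
            )
            home = fld.xy[np.maximum(state.anchor[rw], 0)]
            dhx = home[:, 0] - state.pos[rw, 0]
            dhy = home[:, 1] - state.pos[rw, 1]
            far = loyal & (
                np.hypot(dhx, dhy) > cfg.behaviour.home_radius_m
            )
            if far.any():
                state.heading[rw[far]] = np.arctan2(dhy[far], dhx[far])
            # agents that exhausted their neighbourhood roam the habitat at
            # large instead, steering back whenever they drift out of it
            x0, y0, x1, y1 = state.bbox
            px, py = state.pos[rw, 0], state.pos[rw, 1]
            stray = (
                searching
                & ~loyal
                & ((px < x0) | (px > x1) | (py < y0) | (py > y1))
            )
            if stray.any():
                tx = np.clip(px[stray], x0, x1)
                ty = np.clip(py[stray], y0, y1)
                state.heading[rw[stray]] = np.arctan2(
                    ty - py[stray], tx - px[stray]
                )
            swerve = rng.uniform(-fp.max_turn, fp.max_turn, len(rw))
            speed = bhv.sample_speeds(rng, len(rw), fp)
            new_pos, new_head = bhv.displace(
                state.pos[rw], state.heading[rw], speed, swerve, cfg.step_s
            )
            new_pos, new_head = bhv.reflect_into_plane(
                new_pos, new_head, fld.plane_size
            )
            state.pos[rw] = new_pos
            state.heading[rw] = new_head % (2 * np.pi)

        # goal-directed flight toward chosen roosts
        ft = np.flatnonzero(state.mode == int(Mode.FLYING_TO))
        arrivals: list[int] = []
        if len(ft):
            tpos = fld.xy[state.target[ft]]
            diff = tpos - state.pos[ft]
            dist = np.hypot(diff[:, 0], diff[:, 1])
            speed = bhv.sample_speeds(rng, len(ft), fp) * cfg.step_s
            reach = dist <= speed
            move = ~reach
            if move.any():
                unit = diff[move] / dist[move, None]
                state.pos[ft[move]] += unit * speed[move, None]
                state.heading[ft[move]] = np.arctan2(unit[:, 1], unit[:, 0])
            arrivals = [int(i) for i in ft[reach]]

        for i in arrivals:
            roost = int(state.target[i])
            state.pos[i] = fld.xy[roost]
            if sunrise_phase:
                state._enter_roost(i, roost, t)
            else:
                state._begin_signalling(i, roost, t)

        # foraging windows closing
        done = np.flatnonzero(
            (state.mode == int(Mode.FORAGING)) & (state.timer <= t)
        )
        for i in done:
            state._set_mode(int(i), Mode.SEARCHING, t)

        # roost selection by agents in SEARCHING mode
        if not sunrise_phase:
            searchers = np.flatnonzero(state.mode == int(Mode.SEARCHING))
            if len(searchers):
                _searching_decisions(state, searchers, t)

        # swarming bouts elapsing: a bout ends when its base time plus the
        # live co-swarming extension (NSB^2/2) has passed.  Each entry
        # shrinks the extension for the bats still aloft, so a stalled swarm
        # collapses into the roost as a cascade within the same step.
        if not sunrise_phase:
            touched: set[int] = set()
            while True:
                sig = np.flatnonzero(state.mode == int(Mode.SIGNALLING))
                if not len(sig):
                    break
                ext = fld.n_signalling[state.target[sig]] ** 2 / 2.0
                expiring = sig[state.timer[sig] + ext <= t]
                if not len(expiring):
                    break
                for i in expiring:
                    i = int(i)
                    roost = int(state.target[i])
                    fld.n_signalling[roost] -= 1
                    state._enter_roost(i, roost, t)
                    touched.add(roost)
            for roost in sorted(touched):
                if fld.n_signalling[roost] == 0 and fld.n_roosting[roost] > 0:
                    state._dissolve_if_below_threshold(roost, t)

        # daily snapshot and early exit once the night has settled
        if records is None and np.all(state.mode == int(Mode.IN_ROOST)):
            if t > cfg.record_after_s:
                records = _snapshot(state)
                break
            if not np.any(fld.n_signalling):
                # nothing can change until the snapshot opens
                t = cfg.record_after_s
                records = _snapshot(state)
                break

    # forced housing at cycle end for agents still in transit
    for i in np.flatnonzero(state.mode != int(Mode.IN_ROOST)):
        i = int(i)
        roost = int(state.target[i]) if state.target[i] >= 0 else int(
            state.day_roost[i]
        )
        if state.mode[i] == int(Mode.SIGNALLING):
            fld.n_signalling[roost] -= 1
        state._enter_roost(i, roost, cycle)
    if records is None:
        records = _snapshot(state)
    return records


def _end_of_day(state: EngineState) -> None:
    """16-h daytime block: excrement dynamics and memory penalization."""
    cfg = state.config
    state.day_roost[:] = state.current_roost
    daytime_excrement_update(state.field, state.field.n_roosting, cfg.daytime_s)
    b = cfg.behaviour
    for i in range(cfg.n_agents):
        state.memory[i] = bhv.update_memory(
            state.memory[i],
            int(state.current_roost[i]),
            state.day,
            growth=b.pd_growth,
            decay=b.pd_decay,
            pd_max=b.pd_max,
        )


def run_season(
    config: SimulationConfig,
    field: CavityField | None = None,
    grid: HexGrid | None = None,
    replicate: int = 0,
    seed: int | None = None,
) -> SimulationResult:
    """Run n_days sequential cycles with persistent excrement loads and memory."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    env_ss, sim_ss = ss.spawn(2)
    if field is None:
        env = config.environment
        field, grid = generate_synthetic_environment(
            n_cavities=env.n_cavities,
            seed=np.random.default_rng(env_ss),
            count_profile=env.count_profile,
            height_means=env.height_means,
            height_sd=env.height_sd,
            grid=grid,
        )
    else:
        field.excrement[:] = 0.0
        field.reset_occupancy()
    rng = np.random.default_rng(sim_ss)
    state = initialize_season(config, field, rng)
    rows: list[DailyRoostRecord] = []
    for day in range(config.n_days):
        state.day = day
        rows.extend(run_cycle(state))
        _end_of_day(state)
    records = pd.DataFrame(
        [
            (r.day, r.cavity_id, r.group_size, r.roost_height, r.x, r.y,
             r.is_maximum_group)
            for r in rows
        ],
        columns=RECORD_COLUMNS,
    )
    return SimulationResult(
        records=records,
        config=config,
        seed=seed,
        replicate=replicate,
        transitions=state.transitions if config.track_transitions else None,
    )


def run_replicates(
    config: SimulationConfig,
    n_replicates: int = 6,
    field: CavityField | None = None,
    grid: HexGrid | None = None,
) -> list[SimulationResult]:
    """Independent replicate seasons with seeds derived from the config seed."""
    seeds = [
        int(s)
        for s in np.random.SeedSequence(config.seed).generate_state(n_replicates)
        % (2**31)
    ]
    results = []
    for rep, seed in enumerate(seeds):
        fld = None
        if field is not None:
            fld = CavityField(
                field.ids.copy(),
                field.xy.copy(),
                field.height.copy(),
                plane_size=field.plane_size,
            )
        results.append(
            run_season(config, field=fld, grid=grid, replicate=rep, seed=seed)
        )
    return results


def switching_distances(records: pd.DataFrame) -> np.ndarray:
    """Distances between the maximum-group roosts of consecutive days."""
    maxg = (
        records[records["is_maximum_group"]]
        .sort_values("day")
        .drop_duplicates("day")
        .set_index("day")
    )
    out = []
    for day in maxg.index[:-1]:
        if day + 1 in maxg.index:
            a = maxg.loc[day, ["x", "y"]].to_numpy(float)
            b = maxg.loc[day + 1, ["x", "y"]].to_numpy(float)
            out.append(float(np.hypot(*(a - b))))
    return np.asarray(out)
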