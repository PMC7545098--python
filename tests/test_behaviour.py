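"""Agent kinematics, perception, signalling arithmetic, GST and memory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from roostsim.behaviour import (
    AgentState,
    FlightParams,
    MemoryEntry,
    Mode,
    ThresholdParams,
    displace,
    evaluate_roost,
    group_size_threshold,
    memory_permits,
    perceive_cavities,
    perceive_signallers,
    perception_mask,
    reflect_into_plane,
    sample_speeds,
    signalling_extension,
    signalling_time,
    step_movement,
    update_memory,
)
from roostsim.environment import Cavity, CavityField, QualityWeights


class TestMovement:
    def test_zero_swerve_moves_exactly_along_heading(self):
        pos, heading = displace(
            np.array([[100.0, 100.0]]), np.array([0.7]), np.array([5.0]),
            np.array([0.0]),
        )
        assert heading[0] == pytest.approx(0.7)
        expected = [100 + 5 * math.cos(0.7), 100 + 5 * math.sin(0.7)]
        assert np.allclose(pos[0], expected)

    def test_speed_bounds_hold_for_large_sample(self, rng, flight):
        s = sample_speeds(rng, 100_000, flight)
        assert s.min() >= 2.5
        assert s.max() <= 11.1

    def test_speed_median_matches_species_value(self, rng, flight):
        s = sample_speeds(rng, 100_000, flight)
        assert np.median(s) == pytest.approx(3.7, abs=0.1)

    def test_step_magnitude_within_flight_envelope(self, rng, flight):
        agent = AgentState(0, (4500.0, 4500.0), 0.3, mode=Mode.SEARCHING)
        for _ in range(200):
            before = np.array(agent.position)
            step_movement(agent, flight, 1.0, rng)
            d = np.hypot(*(np.array(agent.position) - before))
            assert 2.5 - 1e-9 <= d <= 11.1 + 1e-9

    def test_reflection_keeps_agents_inside_plane(self, rng, flight):
        agent = AgentState(0, (2.0, 2.0), math.pi * 1.25, mode=Mode.SEARCHING)
        for _ in range(500):
            step_movement(agent, flight, 1.0, rng)
            x, y = agent.position
            assert 0 <= x <= 9000 and 0 <= y <= 9000

    def test_roosting_agent_cannot_fly(self, rng, flight):
        agent = AgentState(0, (100.0, 100.0), 0.0, mode=Mode.IN_ROOST)
        with pytest.raises(ValueError):
            step_movement(agent, flight, 1.0, rng)


def _brute_force_fop(position, heading, points, params):
    """Independent scalar re-derivation of the perception geometry."""
    out = []
    half = math.radians(params.fop_angle) / 2
    for j, (px, py) in enumerate(points):
        dx, dy = px - position[0], py - position[1]
        dist = math.hypot(dx, dy)
        if dist > params.fop_range:
            continue
        if dist == 0.0:
            out.append(j)
            continue
        rel = math.atan2(dy, dx) - heading
        while rel > math.pi:
            rel -= 2 * math.pi
        while rel < -math.pi:
            rel += 2 * math.pi
        if abs(rel) <= half:
            out.append(j)
    return out


class TestPerception:
    def test_cavity_dead_ahead_detected(self, flight):
        mask = perception_mask(
            np.array([0.0, 0.0]), 0.0, np.array([[100.0, 0.0]]), flight
        )
        assert mask[0]

    def test_cavity_beyond_range_missed(self, flight):
        for ang in np.linspace(0, 2 * math.pi, 8):
            pt = 160.0 * np.array([[math.cos(ang), math.sin(ang)]])
            assert not perception_mask(np.zeros(2), 0.0, pt, flight)[0]

    def test_cavity_in_blind_cone_behind_missed(self, flight):
        # 180 degrees off the heading falls inside the 90-degree blind cone
        mask = perception_mask(
            np.array([0.0, 0.0]), 0.0, np.array([[-50.0, 0.0]]), flight
        )
        assert not mask[0]

    def test_matches_brute_force_oracle_on_random_scenes(self, flight):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            pos = rng.uniform(0, 1000, 2)
            heading = rng.uniform(0, 2 * math.pi)
            pts = rng.uniform(0, 1000, (25, 2))
            mask = perception_mask(pos, heading, pts, flight)
            assert sorted(np.flatnonzero(mask)) == _brute_force_fop(
                pos, heading, pts, flight
            )

    def test_perceive_cavities_uses_agent_state(self, small_field, flight):
        agent = AgentState(
            0, (4400.0, 4500.0), 0.0, mode=Mode.SEARCHING
        )  # facing along the cavity line
        idx = perceive_cavities(agent, small_field, flight)
        # cavities at 0..150 m ahead are visible
        assert list(idx) == [0, 1, 2, 3, 4, 5]


class TestReceiverChoice:
    def test_single_signaller_in_range_selected(self):
        got = perceive_signallers(
            np.array([0.0, 0.0]),
            roost_ids=np.array([7]),
            roost_xy=np.array([[50.0, 0.0]]),
            radii=np.array([90.0]),
            n_signallers=np.array([1]),
        )
        assert got == 7

    def test_larger_swarm_wins(self):
        got = perceive_signallers(
            np.array([0.0, 0.0]),
            roost_ids=np.array([1, 2]),
            roost_xy=np.array([[50.0, 0.0], [-60.0, 0.0]]),
            radii=np.array([90.0, 90.0]),
            n_signallers=np.array([3, 5]),
        )
        assert got == 2

    def test_tie_breaks_by_distance_then_id(self):
        got = perceive_signallers(
            np.array([0.0, 0.0]),
            roost_ids=np.array([5, 9]),
            roost_xy=np.array([[60.0, 0.0], [40.0, 0.0]]),
            radii=np.array([90.0, 90.0]),
            n_signallers=np.array([2, 2]),
        )
        assert got == 9  # nearest of the tied swarms
        got = perceive_signallers(
            np.array([0.0, 0.0]),
            roost_ids=np.array([9, 5]),
            roost_xy=np.array([[40.0, 0.0], [40.0, 0.0]]),
            radii=np.array([90.0, 90.0]),
            n_signallers=np.array([2, 2]),
        )
        assert got == 5  # equal distance: lowest id

    def test_none_when_out_of_every_radius(self):
        got = perceive_signallers(
            np.array([0.0, 0.0]),
            roost_ids=np.array([1]),
            roost_xy=np.array([[120.0, 0.0]]),
            radii=np.array([100.0]),
            n_signallers=np.array([4]),
        )
        assert got is None


class TestRoostEvaluation:
    def test_good_quality_no_memory_accepts(self):
        cav = Cavity(0, 0, 0, 11.0, excrement_load=0.0)
        assert evaluate_roost(
            cav, 16.0, QualityWeights(), 30.0, np.empty((0, 2)), np.empty(0)
        )

    def test_threshold_is_strict(self):
        # QR == 30 exactly must be rejected
        cav = Cavity(0, 0, 0, 16.0, excrement_load=100.0)  # QR = 50*1 + 0 = 50
        cav2 = Cavity(0, 0, 0, 9.6, excrement_load=100.0)  # QR = 30 exactly
        w = QualityWeights()
        assert evaluate_roost(cav, 16.0, w, 30.0, np.empty((0, 2)), np.empty(0))
        assert not evaluate_roost(cav2, 16.0, w, 30.0, np.empty((0, 2)), np.empty(0))

    def test_memory_penalization_blocks_nearby_cavity(self):
        cav = Cavity(0, 40.0, 0.0, 15.0, excrement_load=0.0)  # QR = 80+
        assert not evaluate_roost(
            cav, 16.0, QualityWeights(), 30.0,
            np.array([[0.0, 0.0]]), np.array([100.0]),
        )

    def test_memory_permits_brute_force(self, rng):
        for _ in range(200):
            cav = rng.uniform(0, 500, 2)
            pens = rng.uniform(0, 500, (4, 2))
            pds = rng.uniform(0, 150, 4)
            expected = all(
                math.hypot(*(cav - p)) > d for p, d in zip(pens, pds)
            )
            assert memory_permits(cav, pens, pds) == expected


class TestSignallingTimes:
    def test_base_time_formula(self):
        cav = Cavity(0, 0, 0, 5.0)
        assert signalling_time(cav, 27800.0, 28800.0) == pytest.approx(27.0)

    def test_low_cavity_short_bout(self):
        cav = Cavity(0, 0, 0, 1e-6)
        got = signalling_time(cav, 28300.0, 28800.0)
        assert got == pytest.approx(3.0, abs=1e-3)  # 1 + 0 + 1000/500

    def test_each_roosting_bat_adds_one_second(self):
        a = Cavity(0, 0, 0, 5.0, n_roosting=3)
        b = Cavity(0, 0, 0, 5.0, n_roosting=4)
        assert signalling_time(b, 1000.0, 28800.0) - signalling_time(
            a, 1000.0, 28800.0
        ) == pytest.approx(1.0)

    def test_no_time_after_sunrise(self):
        with pytest.raises(ValueError):
            signalling_time(Cavity(0, 0, 0, 5.0), 28800.0, 28800.0)

    @pytest.mark.parametrize("nsb,expected", [(0, 0.0), (2, 2.0), (4, 8.0)])
    def test_extension_quadratic_in_swarm_size(self, nsb, expected):
        cav = Cavity(0, 0, 0, 5.0, n_signalling=nsb)
        assert signalling_extension(cav) == expected


class TestGroupSizeThreshold:
    def test_full_threshold_before_midnight(self):
        p = ThresholdParams()
        for t in (0.0, 5000.0, 10800.0):
            assert group_size_threshold(t, p) == 100.0

    def test_published_parameter_point(self):
        p = ThresholdParams(a=10, b=100, o=10800, t_sim=28800)
        assert group_size_threshold(19800.0, p) == pytest.approx(10.0)

    def test_continuity_at_decay_onset(self):
        p = ThresholdParams()
        assert group_size_threshold(p.o, p) == pytest.approx(
            group_size_threshold(p.o + 1e-6, p), abs=1e-3
        )

    @given(st.floats(min_value=0.0, max_value=28800.0))
    @settings(max_examples=200, deadline=None)
    def test_clamped_to_group_size_bounds(self, t):
        p = ThresholdParams()
        gst = group_size_threshold(t, p)
        assert p.a <= gst <= p.b

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=28800.0),
            min_size=2, max_size=2, unique=True,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_non_increasing_in_time(self, ts):
        p = ThresholdParams()
        t1, t2 = sorted(ts)
        assert group_size_threshold(t1, p) >= group_size_threshold(t2, p)

    def test_outside_cycle_rejected(self):
        with pytest.raises(ValueError):
            group_size_threshold(-1.0, ThresholdParams())


class TestMemoryUpdate:
    def test_fresh_roost_gets_positive_radius(self):
        mem = update_memory([], current_roost=4, day=0)
        assert len(mem) == 1
        assert mem[0].roost_id == 4
        assert mem[0].penalization_distance > 0

    def test_unused_roost_decays_away(self):
        mem = [MemoryEntry(4, 50.0, 0)]
        mem = update_memory(mem, current_roost=9, day=1)
        ids = {m.roost_id for m in mem}
        assert 4 not in ids  # 50 - 50 -> dropped
        assert 9 in ids

    def test_radius_never_exceeds_cap(self):
        mem = []
        for day in range(10):
            mem = update_memory(mem, current_roost=1, day=day)
            assert all(m.penalization_distance <= 150.0 for m in mem)
        assert mem[0].penalization_distance == 150.0

    def test_partial_decay_keeps_entry(self):
        mem = [MemoryEntry(4, 120.0, 0)]
        mem = update_memory(mem, current_roost=None, day=1)
        assert mem[0].penalization_distance == pytest.approx(70.0)
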