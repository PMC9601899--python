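"""Arena geometry, kinematics and sensing."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from bnbot.arena import (
    Arena,
    DEFAULT_PHYSICS,
    Physics,
    RobotState,
    arena_task1,
    arena_task2,
    arena_task3,
    collision_theta,
    light_readings,
    place_robots,
    proximity_readings,
    region_of,
    step_kinematics,
)


class TestKinematics:
    def test_stationary(self):
        arena = arena_task1()
        rob = RobotState(1.0, 1.0, 0.3)
        out = step_kinematics(arena, rob, 0.0, 0.0)
        assert (out.x, out.y) == (1.0, 1.0)
        assert out.heading == pytest.approx(0.3)

    def test_straight_advance_closed_form(self):
        arena = arena_task1()
        rob = RobotState(0.0, 1.5, 0.0)
        out = step_kinematics(arena, rob, 1.0, 1.0)
        ph = DEFAULT_PHYSICS
        assert out.x == pytest.approx(ph.v_max * ph.dt)
        assert out.y == pytest.approx(1.5)
        assert out.heading == pytest.approx(0.0)

    def test_single_wheel_rotation_rate(self):
        arena = arena_task1()
        rob = RobotState(0.0, 1.5, 0.0)
        out = step_kinematics(arena, rob, 0.0, 1.0)
        ph = DEFAULT_PHYSICS
        assert out.heading == pytest.approx(ph.v_max * ph.dt / ph.axle)

    def test_wall_blocks_translation(self):
        arena = arena_task1()
        ph = DEFAULT_PHYSICS
        rob = RobotState(2.0 - ph.radius - 0.001, 0.9, 0.0)  # facing east wall
        out = step_kinematics(arena, rob, 1.0, 1.0)
        assert out.collided
        assert (out.x, out.y) == (rob.x, rob.y)

    def test_robot_blocks_robot(self):
        arena = arena_task1()
        ph = DEFAULT_PHYSICS
        rob = RobotState(1.0, 1.0, 0.0)
        other = np.array([[1.0 + 2 * ph.radius + 0.005, 1.0]])
        out = step_kinematics(arena, rob, 1.0, 1.0, others=other)
        assert out.collided and out.x == rob.x

    def test_never_ends_inside_obstacle(self, rng):
        arena = arena_task1()
        rob = RobotState(-0.8, 0.0, 0.0)  # aimed at the central block
        for _ in range(300):
            l, r = rng.integers(0, 2, 2)
            rob = step_kinematics(arena, rob, float(l), float(r))
            assert arena.contains(rob.pos, margin=DEFAULT_PHYSICS.radius * 0.99)


class TestProximity:
    def test_free_space_all_zero(self):
        arena = arena_task1()
        r = proximity_readings(arena, RobotState(0.0, 1.2, 0.0))
        assert (r == 0).all()
        assert collision_theta(r) == 0.0

    def test_touching_wall_reads_one(self):
        arena = arena_task1()
        ph = DEFAULT_PHYSICS
        rob = RobotState(2.0 - ph.radius, 0.9, 0.0)
        r = proximity_readings(arena, rob)
        assert r[0] == pytest.approx(1.0)

    def test_linear_falloff_half_range(self):
        arena = arena_task1()
        ph = DEFAULT_PHYSICS
        d = ph.prox_range / 2
        rob = RobotState(2.0 - ph.radius - d, 0.9, 0.0)
        r = proximity_readings(arena, rob)
        assert r[0] == pytest.approx(0.5)

    def test_other_robot_detected(self):
        arena = arena_task1()
        ph = DEFAULT_PHYSICS
        rob = RobotState(1.0, 1.0, 0.0)
        other = np.array([[1.0 + 2 * ph.radius + 0.02, 1.0]])
        r = proximity_readings(arena, rob, others=other)
        assert r[0] > 0.5
        assert (r[6:19] == 0).all()

    def test_translation_invariance(self):
        # identical local geometry shifted rigidly gives identical readings
        shift = np.array([3.0, -2.0])
        a0 = arena_task1()
        a1 = Arena(a0.boundary + shift, tuple(o + shift for o in a0.obstacles))
        r0 = proximity_readings(a0, RobotState(1.55, 0.3, 1.1))
        r1 = proximity_readings(a1, RobotState(1.55 + shift[0], 0.3 + shift[1], 1.1))
        np.testing.assert_allclose(r0, r1, atol=1e-12)


class TestLight:
    def test_no_source_all_zero(self):
        assert (light_readings(arena_task1(), RobotState(0, 1, 0)) == 0).all()

    def test_at_source_max_one(self):
        arena = arena_task3()
        rob = RobotState(arena.light[0], arena.light[1], 0.0)
        assert light_readings(arena, rob).max() == pytest.approx(1.0)

    def test_monotone_gradient(self):
        arena = arena_task3()
        near = RobotState(1.0, 0.0, 0.0)
        far = RobotState(-1.0, 0.0, 0.0)
        assert light_readings(arena, near).max() > light_readings(arena, far).max()

    def test_inverse_square_quarters(self):
        arena = arena_task3()
        ph = Physics(light_falloff="inverse_square")
        lx = arena.light[0]
        r1 = light_readings(arena, RobotState(lx - 1.0, 0.0, 0.0), ph)
        r2 = light_readings(arena, RobotState(lx - 2.0, 0.0, 0.0), ph)
        assert r2[0] == pytest.approx(r1[0] / 4)


class TestRegionsAndPlacement:
    def test_task2_half_open_split(self):
        arena = arena_task2()
        assert region_of(arena, RobotState(-0.01, 0, 0)) == "left"
        assert region_of(arena, RobotState(0.0, 0, 0)) == "right"

    def test_task3_zones(self):
        arena = arena_task3()
        assert region_of(arena, RobotState(-2.0, 0, 0)) == "blue"
        assert region_of(arena, RobotState(0.0, 0, 0)) == "neutral"
        assert region_of(arena, RobotState(2.0, 0, 0)) == "green"

    def test_factory_invariants(self):
        for arena in (arena_task1(), arena_task2(), arena_task3()):
            bound = Polygon(arena.boundary)
            for obs in arena.obstacles:
                assert bound.contains(Polygon(obs))
        assert arena_task3().light is not None

    def test_containment_matches_shapely(self, rng):
        arena = arena_task3()
        poly = Polygon(arena.boundary)
        obst = [Polygon(o) for o in arena.obstacles]
        for _ in range(200):
            p = rng.uniform(-3, 3, 2)
            expected = poly.covers(Point(p)) and not any(
                o.contains(Point(p)) for o in obst
            )
            got = arena.contains(p)
            if abs(arena.segment_distance(p)) > 1e-9:  # skip exact boundaries
                assert got == expected

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_ten_robots_placed_without_overlap(self, seed):
        arena = arena_task1()
        robots = place_robots(arena, 10, np.random.default_rng(seed))
        ph = DEFAULT_PHYSICS
        for i, a in enumerate(robots):
            assert arena.contains(a.pos, margin=ph.radius)
            for b in robots[i + 1:]:
                assert np.hypot(a.x - b.x, a.y - b.y) >= 2 * ph.radius

    def test_assigned_region_from_placement(self):
        arena = arena_task2()
        robots = place_robots(arena, 5, np.random.default_rng(3),
                              assign_regions=True)
        for rob in robots:
            assert rob.assigned_region == region_of(arena, rob)

    def test_dict_roundtrip(self):
        arena = arena_task3()
        rt = Arena.from_dict(arena.to_dict())
        np.testing.assert_allclose(rt.boundary, arena.boundary)
        assert rt.region_bands == arena.region_bands
        np.testing.assert_allclose(rt.light, arena.light)
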