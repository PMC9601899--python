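"""Minimal 2D robot-arena physics.

A stand-in for the foot-bot simulation: differential-drive discs with 24
proximity rays and 24 light sensors, moving in convex polygonal arenas
with convex polygonal obstacles, virtual regions and an optional light
source.  Three arena factories mirror the task layouts: a square with a
central block (navigation), a rectangle split into two half-arena regions
(region-bound navigation), and an octagon with central obstacles, a blue
pick-up zone, a green deposit zone and a light source over the green zone
(foraging).

Geometry is continuous 2D with the origin at the arena centre.  Region
membership uses half-open x-band boundaries so every pose has exactly one
label.  Physical constants (body radius, wheel speed, sensor range) are
collected in :class:`Physics`; defaults are foot-bot-like and documented
in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "Physics",
    "RobotState",
    "Arena",
    "arena_task1",
    "arena_task2",
    "arena_task3",
    "step_kinematics",
    "proximity_readings",
    "light_readings",
    "region_of",
    "collision_theta",
    "place_robots",
    "SENSOR_ANGLES",
]

#: 24 body-relative sensor bearings at equal angular spacing.
SENSOR_ANGLES = 2.0 * np.pi * np.arange(24) / 24.0
_SENSOR_DIRS = np.stack([np.cos(SENSOR_ANGLES), np.sin(SENSOR_ANGLES)], axis=1)


@dataclass(frozen=True)
class Physics:
    """Physical constants of the robot and sensors.

    dt: control period [s] (10 steps/s); v_max: wheel rim speed at command
    1 [m/s]; axle: wheel separation [m]; radius: body radius [m];
    prox_range: proximity sensor range measured from the body edge [m];
    light_range: distance at which a linear-falloff light reading reaches 0
    [m]; light_falloff: "linear" or "inverse_square"; light_ref: reference
    distance of the inverse-square law [m].
    """

    dt: float = 0.1
    v_max: float = 0.15
    axle: float = 0.14
    radius: float = 0.085
    prox_range: float = 0.10
    light_range: float = 6.0
    light_falloff: str = "linear"
    light_ref: float = 0.05


DEFAULT_PHYSICS = Physics()


@dataclass(frozen=True)
class RobotState:
    """Pose and actuator/task state of one robot."""

    x: float
    y: float
    heading: float
    left: float = 0.0
    right: float = 0.0
    hook: bool = False
    carrying: bool = False
    assigned_region: str | None = None
    collided: bool = False

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y])


def _poly_segments(poly: np.ndarray) -> np.ndarray:
    v = np.asarray(poly, float)
    return np.stack([v, np.roll(v, -1, axis=0)], axis=1)  # (V, 2, 2)


def _point_in_convex(poly: np.ndarray, p: np.ndarray) -> bool:
    """Point-in-convex-polygon via edge cross products (CCW vertices)."""
    v = np.asarray(poly, float)
    e = np.roll(v, -1, axis=0) - v
    w = np.asarray(p, float) - v
    cross = e[:, 0] * w[:, 1] - e[:, 1] * w[:, 0]
    return bool((cross >= 0).all())


def _ensure_ccw(poly: np.ndarray) -> np.ndarray:
    v = np.asarray(poly, float)
    area2 = np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
    return v if area2 > 0 else v[::-1]


class Arena:
    """A convex boundary polygon, convex obstacles, x-band virtual regions
    and an optional light source.

    ``region_bands`` is a sequence of ``(x_upper, label)`` pairs sorted by
    ``x_upper`` (last one ``inf``); a pose with ``x < x_upper`` of the first
    matching band gets that label, giving half-open boundaries.
    """

    def __init__(
        self,
        boundary: np.ndarray,
        obstacles: tuple[np.ndarray, ...] = (),
        region_bands: tuple[tuple[float, str], ...] = ((np.inf, "arena"),),
        light: tuple[float, float] | None = None,
        name: str = "arena",
    ) -> None:
        self.boundary = _ensure_ccw(boundary)
        self.obstacles = tuple(_ensure_ccw(o) for o in obstacles)
        self.region_bands = tuple(region_bands)
        self.light = None if light is None else np.asarray(light, float)
        self.name = name
        self._validate()
        segs = [_poly_segments(self.boundary)]
        segs += [_poly_segments(o) for o in self.obstacles]
        self.segments = np.concatenate(segs, axis=0)
        self._seg_p = self.segments[:, 0]
        self._seg_d = self.segments[:, 1] - self.segments[:, 0]
        self._seg_len2 = np.maximum((self._seg_d**2).sum(axis=1), 1e-300)

    def _validate(self) -> None:
        bound = Polygon(self.boundary)
        if not bound.is_valid:
            raise ValueError("invalid boundary polygon")
        if bound.convex_hull.area > bound.area * (1 + 1e-9):
            raise ValueError("boundary must be convex")
        for obs in self.obstacles:
            op = Polygon(obs)
            if not bound.contains(op):
                raise ValueError("obstacles must lie strictly inside the boundary")
        uppers = [u for u, _ in self.region_bands]
        if sorted(uppers) != list(uppers) or uppers[-1] != np.inf:
            raise ValueError("region bands must be sorted with a final inf band")

    # -- geometry queries -------------------------------------------------

    def contains(self, p: np.ndarray, margin: float = 0.0) -> bool:
        """True if a disc of radius ``margin`` at ``p`` is in free space."""
        p = np.asarray(p, float)
        if not _point_in_convex(self.boundary, p):
            return False
        for obs in self.obstacles:
            if _point_in_convex(obs, p):
                return False
        if margin > 0.0 and self.segment_distance(p) < margin:
            return False
        return True

    def segment_distance(self, p: np.ndarray) -> float:
        """Distance from ``p`` to the nearest wall/obstacle segment."""
        w = np.asarray(p, float) - self._seg_p
        t = np.clip((w * self._seg_d).sum(axis=1) / self._seg_len2, 0.0, 1.0)
        closest = self._seg_p + t[:, None] * self._seg_d
        return float(np.sqrt(((p - closest) ** 2).sum(axis=1).min()))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "boundary": self.boundary.tolist(),
            "obstacles": [o.tolist() for o in self.obstacles],
            "region_bands": [
                [None if not np.isfinite(u) else u, lab] for u, lab in self.region_bands
            ],
            "light": None if self.light is None else self.light.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Arena":
        bands = tuple(
            (np.inf if u is None else float(u), lab) for u, lab in d["region_bands"]
        )
        return cls(
            np.array(d["boundary"]),
            tuple(np.array(o) for o in d["obstacles"]),
            bands,
            None if d.get("light") is None else tuple(d["light"]),
            d.get("name", "arena"),
        )


def _square(cx: float, cy: float, side: float) -> np.ndarray:
    h = side / 2.0
    return np.array(
        [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]]
    )


def arena_task1(side: float = 4.0, obstacle_side: float = 1.0) -> Arena:
    """Square arena with a central square obstacle (navigation task)."""
    return Arena(
        _square(0, 0, side),
        (_square(0, 0, obstacle_side),),
        ((np.inf, "arena"),),
        name="task1",
    )


def arena_task2(
    width: float = 5.0, height: float = 3.0, obstacle_side: float = 1.0
) -> Arena:
    """Rectangular arena, central obstacle, two half-arena virtual regions
    split at x = 0 (half-open: x < 0 is "left", x >= 0 is "right")."""
    w, h = width / 2.0, height / 2.0
    boundary = np.array([[-w, -h], [w, -h], [w, h], [-w, h]])
    return Arena(
        boundary,
        (_square(0, 0, obstacle_side),),
        ((0.0, "left"), (np.inf, "right")),
        name="task2",
    )


def arena_task3(
    circumradius: float = 2.5,
    obstacle_side: float = 0.8,
    zone_x: float = 1.3,
) -> Arena:
    """Octagonal arena with two central obstacles, a blue pick-up zone
    (x < -zone_x), a green deposit zone (x >= zone_x) and a light source on
    the boundary over the green zone (foraging task)."""
    ang = np.pi / 8 + np.pi / 4 * np.arange(8)
    boundary = circumradius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    obstacles = (
        _square(0.0, 0.9, obstacle_side),
        _square(0.0, -0.9, obstacle_side),
    )
    light_x = circumradius * np.cos(np.pi / 8)  # mid-point of the east face
    return Arena(
        boundary,
        obstacles,
        ((-zone_x, "blue"), (zone_x, "neutral"), (np.inf, "green")),
        light=(light_x, 0.0),
        name="task3",
    )


# -- sensing ---------------------------------------------------------------


def _ray_segment_hits(origin: np.ndarray, dirs: np.ndarray, arena: Arena) -> np.ndarray:
    """Nearest positive ray parameter t per ray against all segments."""
    p, d = arena._seg_p, arena._seg_d
    denom = dirs[:, None, 0] * d[None, :, 1] - dirs[:, None, 1] * d[None, :, 0]
    rel = p - origin  # (S, 2)
    t_num = rel[None, :, 0] * d[None, :, 1] - rel[None, :, 1] * d[None, :, 0]
    u_num = rel[None, :, 0] * dirs[:, None, 1] - rel[None, :, 1] * dirs[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = t_num / denom
        u = u_num / denom
    valid = (np.abs(denom) > 1e-12) & (u >= 0.0) & (u <= 1.0) & (t > 0.0)
    return np.where(valid, t, np.inf).min(axis=1)


def _ray_disc_hits(
    origin: np.ndarray, dirs: np.ndarray, centers: np.ndarray, radius: float
) -> np.ndarray:
    if centers.size == 0:
        return np.full(len(dirs), np.inf)
    oc = centers[None, :, :] - origin  # (1, C, 2)
    b = dirs[:, None, 0] * oc[..., 0] + dirs[:, None, 1] * oc[..., 1]
    c = (oc**2).sum(axis=-1) - radius**2
    disc = b * b - c
    ok = disc >= 0.0
    t = b - np.sqrt(np.where(ok, disc, 0.0))
    return np.where(ok & (t > 0.0), t, np.inf).min(axis=1)


def _sensor_dirs(heading: float) -> np.ndarray:
    c, s = np.cos(heading), np.sin(heading)
    rot = np.array([[c, -s], [s, c]])
    return _SENSOR_DIRS @ rot.T


def proximity_readings(
    arena: Arena,
    robot: RobotState,
    others: np.ndarray | tuple = (),
    physics: Physics = DEFAULT_PHYSICS,
) -> np.ndarray:
    """24 proximity readings in [0, 1]: rays at equal angular spacing
    around the body, reading = max(0, 1 - d/range) where d is the distance
    from the body edge to the nearest wall, obstacle or other robot."""
    origin = robot.pos
    dirs = _sensor_dirs(robot.heading)
    t = _ray_segment_hits(origin, dirs, arena)
    others = np.asarray(others, float).reshape(-1, 2)
    if others.size:
        t = np.minimum(t, _ray_disc_hits(origin, dirs, others, physics.radius))
    d = t - physics.radius
    with np.errstate(invalid="ignore"):
        readings = 1.0 - d / physics.prox_range
    return np.clip(np.nan_to_num(readings, nan=0.0, neginf=0.0), 0.0, 1.0)


def light_readings(
    arena: Arena, robot: RobotState, physics: Physics = DEFAULT_PHYSICS
) -> np.ndarray:
    """24 light readings in [0, 1]: intensity decreasing with distance to
    the source, modulated per sensor by the clamped cosine of the angle
    between the sensor bearing and the source direction (occlusion is
    ignored).  All-zero when the arena has no light source."""
    if arena.light is None:
        return np.zeros(24)
    vec = arena.light - robot.pos
    d = float(np.hypot(*vec))
    if d < 1e-9:
        return np.ones(24)
    if physics.light_falloff == "inverse_square":
        inten = min(1.0, (physics.light_ref / d) ** 2)
    else:
        inten = max(0.0, 1.0 - d / physics.light_range)
    bearing = np.arctan2(vec[1], vec[0])
    align = np.clip(np.cos(robot.heading + SENSOR_ANGLES - bearing), 0.0, 1.0)
    return align * inten


def region_of(arena: Arena, robot: RobotState | np.ndarray) -> str:
    """Label of the virtual region containing the pose (half-open bands)."""
    x = robot.x if isinstance(robot, RobotState) else float(np.asarray(robot)[0])
    for upper, label in arena.region_bands:
        if x < upper:
            return label
    return arena.region_bands[-1][1]


def collision_theta(readings: np.ndarray, task: int | None = None) -> float:
    """Collision proxy theta: the maximum of the 24 normalized proximity
    readings.  (The foraging task's doubled penalty is applied in the
    objective itself, not here.)"""
    return float(np.max(readings))


# -- motion ----------------------------------------------------------------


def step_kinematics(
    arena: Arena,
    robot: RobotState,
    l: float,
    r: float,
    others: np.ndarray | tuple = (),
    physics: Physics = DEFAULT_PHYSICS,
) -> RobotState:
    """Differential-drive update over one control period.

    Linear velocity ``v_max (l + r) / 2`` along the current heading,
    angular velocity ``v_max (r - l) / axle``.  If the candidate position
    would overlap a wall, obstacle or another robot the translation is
    blocked (position clamped, ``collided`` flagged); rotation still
    applies.
    """
    if physics.dt <= 0:
        raise ValueError("dt must be > 0")
    v = physics.v_max * (l + r) / 2.0
    w = physics.v_max * (r - l) / physics.axle
    nx = robot.x + v * physics.dt * np.cos(robot.heading)
    ny = robot.y + v * physics.dt * np.sin(robot.heading)
    nh = (robot.heading + w * physics.dt + np.pi) % (2.0 * np.pi) - np.pi
    cand = np.array([nx, ny])
    blocked = False
    if v != 0.0:
        if arena.segment_distance(cand) < physics.radius or not _point_in_convex(
            arena.boundary, cand
        ):
            blocked = True
        else:
            others = np.asarray(others, float).reshape(-1, 2)
            if others.size and (
                np.hypot(others[:, 0] - nx, others[:, 1] - ny).min()
                < 2.0 * physics.radius
            ):
                blocked = True
    if blocked:
        nx, ny = robot.x, robot.y
    return replace(
        robot, x=float(nx), y=float(ny), heading=float(nh), left=l, right=r,
        collided=blocked,
    )


def place_robots(
    arena: Arena,
    count: int,
    rng: np.random.Generator,
    physics: Physics = DEFAULT_PHYSICS,
    assign_regions: bool = False,
) -> list[RobotState]:
    """Rejection-sample ``count`` non-overlapping robot poses in free
    space.  With ``assign_regions`` each robot's assigned region is the one
    it is placed in (region-bound navigation)."""
    lo = arena.boundary.min(axis=0)
    hi = arena.boundary.max(axis=0)
    placed: list[RobotState] = []
    attempts = 0
    while len(placed) < count:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place robots without overlap")
        p = lo + rng.random(2) * (hi - lo)
        if not arena.contains(p, margin=physics.radius):
            continue
        if any(
            np.hypot(q.x - p[0], q.y - p[1]) < 2.0 * physics.radius for q in placed
        ):
            continue
        heading = float(rng.uniform(-np.pi, np.pi))
        rob = RobotState(float(p[0]), float(p[1]), heading)
        if assign_regions:
            rob = replace(rob, assigned_region=region_of(arena, rob))
        placed.append(rob)
    return placed
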