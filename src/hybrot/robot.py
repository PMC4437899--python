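"""Differential-drive robot kinematics, arena geometry, and bearing sensing.

The robot is the classic two-wheel unicycle: linear speed v = (vl + vr)/2,
yaw rate ω = (vr − vl)/wheelbase, integrated exactly along circular arcs.
The camera of the physical system is idealized as exact bearing sensing to
the target object placed at the arena center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "RobotState",
    "ArenaConfig",
    "step",
    "bearing_to_object",
    "required_turn",
    "reached",
    "wrap_angle",
]


def wrap_angle(a: float) -> float:
    """Wrap an angle into (−π, π]."""
    a = math.fmod(a, 2 * math.pi)
    if a <= -math.pi:
        a += 2 * math.pi
    elif a > math.pi:
        a -= 2 * math.pi
    return a


@dataclass(frozen=True)
class RobotState:
    x: float = 0.0  # m
    y: float = 0.0  # m
    heading: float = 0.0  # rad, in (−π, π]
    speed: float = 0.05  # m/s, commanded linear speed between decisions

    def __post_init__(self):
        object.__setattr__(self, "heading", wrap_angle(self.heading))


@dataclass(frozen=True)
class ArenaConfig:
    """Square arena with the search object at its center by default."""

    width: float = 2.0  # m
    height: float = 2.0  # m
    object_xy: tuple[float, float] = (1.0, 1.0)
    reach_radius: float = 0.1  # m, closed ball: boundary counts as reached
    start_margin: float = 0.1  # m, corner start poses inset from the walls

    def __post_init__(self):
        ox, oy = self.object_xy
        if not (0 <= ox <= self.width and 0 <= oy <= self.height):
            raise ValueError("object must lie inside the arena")
        if self.reach_radius <= 0:
            raise ValueError("reach radius must be positive")

    @property
    def start_corners(self) -> list[RobotState]:
        # each corner pose faces along a wall with the object ~45° off-heading,
        # alternating left-turn-first and right-turn-first corners so both
        # turn directions are exercised over repeated starts
        m = self.start_margin
        w, h = self.width, self.height
        poses = [
            ((m, m), 0.0),  # east along south wall: object to the left
            ((w - m, m), math.pi),  # west along south wall: object to the right
            ((w - m, h - m), math.pi),  # west along north wall: object to the left
            ((m, h - m), 0.0),  # east along north wall: object to the right
        ]
        return [RobotState(x=x, y=y, heading=hd) for (x, y), hd in poses]

    def clamp(self, state: RobotState) -> RobotState:
        """Clamp a pose to the arena walls (heading unchanged)."""
        x = min(max(state.x, 0.0), self.width)
        y = min(max(state.y, 0.0), self.height)
        if x == state.x and y == state.y:
            return state
        return replace(state, x=x, y=y)


def step(
    state: RobotState,
    vl: float,
    vr: float,
    dt: float,
    wheelbase: float = 0.1,
    arena: ArenaConfig | None = None,
) -> RobotState:
    """Advance the unicycle model by dt seconds with exact arc integration.

    Optionally clamps the resulting pose at the arena walls.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = (vl + vr) / 2.0
    omega = (vr - vl) / wheelbase
    h = state.heading
    if abs(omega) < 1e-12:
        x = state.x + v * dt * math.cos(h)
        y = state.y + v * dt * math.sin(h)
        h_new = h
    else:
        r = v / omega
        h_new = h + omega * dt
        x = state.x + r * (math.sin(h_new) - math.sin(h))
        y = state.y - r * (math.cos(h_new) - math.cos(h))
    out = RobotState(x=x, y=y, heading=wrap_angle(h_new), speed=state.speed)
    if arena is not None:
        out = arena.clamp(out)
    return out


def bearing_to_object(state: RobotState, arena: ArenaConfig) -> float:
    """Signed bearing (rad) from robot heading to the object; positive = left."""
    ox, oy = arena.object_xy
    dx, dy = ox - state.x, oy - state.y
    if dx == 0 and dy == 0:
        return 0.0
    return wrap_angle(math.atan2(dy, dx) - state.heading)


def required_turn(bearing: float, deadband: float) -> str:
    """Ground-truth turn for a bearing: 'left', 'right', or 'none' within the deadband."""
    if deadband < 0:
        raise ValueError("deadband must be non-negative")
    if bearing > deadband:
        return "left"
    if bearing < -deadband:
        return "right"
    return "none"


def reached(state: RobotState, arena: ArenaConfig) -> bool:
    ox, oy = arena.object_xy
    return math.hypot(state.x - ox, state.y - oy) <= arena.reach_radius
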