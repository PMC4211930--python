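"""Reactive search strategies: surge, zigzag casting, spiral casting.

Three pre-programmed strategies, triggered purely by detection events, mirror
the phases of multiphasic pheromone responses in the moth antennal lobe:
baseline firing -> spiraling, On response -> straight upwind surge, Off
response -> crosswind zigzagging.

* ``sp``  — surge + (arithmetic) spiral casting only,
* ``za``  — surge + zigzag casting, then arithmetic spiral after a timeout,
* ``ze``  — surge + zigzag casting, then exponential spiral after a timeout.

Every detection resets the agent into a fresh upwind surge.  When a surge
finishes without a new detection the agent starts zigzagging (``za``/``ze``)
or spiraling (``sp``).  Zigzag legs alternate headings of +/-60 degrees about
upwind; the first crosswind leg is 9 cm and each later leg doubles — on the
ideal path this is the same as doubling at each crossing of the centerline
through the position where zigzagging began, since every leg after the first
crosses it exactly once.  Zigzagging gives up after 19 s and falls back to
spiral casting, which persists until the next detection.

Spirals are ideal Archimedean (radius = b * phase) or logarithmic (radius =
r0 * exp(g * phase)) curves traversed at the constant cruise speed; the phase
is advanced by exact arc-length parameterization so sampled points are never
farther apart than speed * dt.

All headings are measured from +y (upwind); a heading theta moves the agent
along (sin theta, cos theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Mode",
    "ReactiveConfig",
    "AgentState",
    "config_for_strategy",
    "initial_state",
    "on_detection",
    "advance",
    "spiral_point",
]

REACTIVE_STRATEGIES = ("sp", "za", "ze")


class Mode(str, Enum):
    SPIRAL = "spiral"
    SURGE = "surge"
    ZIGZAG = "zigzag"


@dataclass(frozen=True)
class ReactiveConfig:
    """Movement parameters of a reactive strategy.

    Defaults follow the robotic assay: 5 cm surges, +/-60 degree zigzag legs
    starting at 9 cm and doubling, a 19 s zigzag timeout, 5 cm/s cruise
    speed.  Spiral pitches are set so the first loop diameter is about
    0.3 m, comparable to the initial zigzag extent.
    """

    surge_length: float = 0.05
    zigzag_angle_deg: float = 60.0
    zigzag_step0: float = 0.09
    zigzag_timeout: float = 19.0
    speed: float = 0.05
    use_zigzag: bool = True
    spiral_kind: str = "arithmetic"  # 'arithmetic' | 'exponential'
    spiral_pitch: float = 0.024      # b, m/rad (arithmetic)
    spiral_r0: float = 0.075         # initial radius, m (exponential)
    spiral_growth: float = 0.2       # g, 1/rad (exponential)
    spiral_r_start: float = 0.05     # casting entry radius, m (arithmetic)

    def __post_init__(self) -> None:
        for name in ("surge_length", "zigzag_step0", "zigzag_timeout", "speed",
                     "spiral_pitch", "spiral_r0", "spiral_growth"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.zigzag_angle_deg < 90:
            raise ValueError("zigzag_angle_deg must lie strictly between 0 and 90")
        if self.spiral_kind not in ("arithmetic", "exponential"):
            raise ValueError("spiral_kind must be 'arithmetic' or 'exponential'")


def config_for_strategy(strategy: str, **overrides) -> ReactiveConfig:
    """Default configuration for one of the strategies 'sp', 'za', 'ze'."""
    if strategy == "sp":
        base = dict(use_zigzag=False, spiral_kind="arithmetic",
                    spiral_r_start=0.05)
    elif strategy == "za":
        # casting picks up at the spatial scale of the preceding search
        # phase: wider entry after zigzag legs than after a 5 cm surge
        base = dict(use_zigzag=True, spiral_kind="arithmetic",
                    spiral_r_start=0.1)
    elif strategy == "ze":
        base = dict(use_zigzag=True, spiral_kind="exponential")
    else:
        raise ValueError(f"unknown reactive strategy {strategy!r}")
    base.update(overrides)
    return ReactiveConfig(**base)


@dataclass
class AgentState:
    """Mutable kinematic state of a reactive agent.

    ``mode_clock`` counts seconds since the current mode was entered;
    ``dist_in_phase`` tracks progress through the current surge or zigzag
    leg; ``zigzag_axis_x`` is the x of the centerline through the position
    where the current zigzag bout began.
    """

    position: np.ndarray
    heading: float = 0.0
    mode: Mode = Mode.SPIRAL
    mode_clock: float = 0.0
    dist_in_phase: float = 0.0
    zigzag_leg_index: int = 0
    zigzag_side: int = 1
    zigzag_axis_x: float = 0.0
    n_crossings: int = 0
    spiral_phase: float = 0.0
    spiral_center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    spiral_rot: float = 0.0  # rotation of the spiral frame, rad
    spiral_dir: int = -1     # handedness of the *next* spiral bout (+1 CCW)


def initial_state(position, cfg: ReactiveConfig) -> AgentState:
    """Agent at rest in baseline spiral casting at ``position``."""
    state = AgentState(position=np.asarray(position, dtype=float).copy())
    _enter_spiral(state, cfg)
    return state


def on_detection(state: AgentState, cfg: ReactiveConfig) -> AgentState:
    """A detection (from any mode) restarts a straight upwind surge."""
    state.mode = Mode.SURGE
    state.heading = 0.0
    state.mode_clock = 0.0
    state.dist_in_phase = 0.0
    state.zigzag_leg_index = 0
    state.zigzag_side = 1
    state.zigzag_axis_x = float(state.position[0])
    state.n_crossings = 0
    return state


def spiral_point(phase: float, cfg: ReactiveConfig) -> np.ndarray:
    """Offset of the spiral point at ``phase`` (rad) from the spiral center."""
    if phase < 0:
        raise ValueError("phase must be non-negative")
    if cfg.spiral_kind == "arithmetic":
        r = cfg.spiral_pitch * phase
    else:
        r = cfg.spiral_r0 * math.exp(cfg.spiral_growth * phase)
    return np.array([r * math.cos(phase), r * math.sin(phase)])


def _arith_arc_length(phase: float, b: float) -> float:
    # ds = b sqrt(1 + phi^2) dphi, closed form
    return 0.5 * b * (phase * math.sqrt(1.0 + phase * phase) + math.asinh(phase))


def _phase_after_arc(phase: float, arc: float, cfg: ReactiveConfig) -> float:
    """Phase reached after traveling ``arc`` meters along the spiral."""
    if cfg.spiral_kind == "exponential":
        g, r0 = cfg.spiral_growth, cfg.spiral_r0
        c = r0 * math.sqrt(1.0 + g * g) / g
        return math.log(math.exp(g * phase) + arc / c) / g
    b = cfg.spiral_pitch
    target = _arith_arc_length(phase, b) + arc
    phi = phase + arc / (b * math.sqrt(1.0 + phase * phase))  # first guess
    for _ in range(50):
        f = _arith_arc_length(phi, b) - target
        fp = b * math.sqrt(1.0 + phi * phi)
        step = f / fp
        phi -= step
        if abs(step) < 1e-13:
            break
    return phi


def _spiral_tangent(phase: float, cfg: ReactiveConfig) -> np.ndarray:
    """Unnormalized tangent d(offset)/d(phase) in the spiral's local frame."""
    if cfg.spiral_kind == "arithmetic":
        r = cfg.spiral_pitch * phase
        dr = cfg.spiral_pitch
    else:
        r = cfg.spiral_r0 * math.exp(cfg.spiral_growth * phase)
        dr = cfg.spiral_growth * r
    c, s = math.cos(phase), math.sin(phase)
    return np.array([dr * c - r * s, dr * s + r * c])


def _rotate(vec: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def _mirror(vec: np.ndarray, direction: int) -> np.ndarray:
    """Flip the local-frame y component for clockwise (direction=-1) spirals."""
    return np.array([vec[0], direction * vec[1]])


def _enter_spiral(state: AgentState, cfg: ReactiveConfig) -> None:
    state.mode = Mode.SPIRAL
    state.mode_clock = 0.0
    state.dist_in_phase = 0.0
    # A robot turns with a finite radius: the arithmetic spiral enters at the
    # phase where its radius equals spiral_r_start instead of collapsing to
    # r = 0 (the exponential starts at r0 by construction).  Casting starts
    # crosswind: the spiral frame is rotated so the entry tangent points 90
    # degrees off the agent's current heading, on a side that alternates
    # between bouts so casting has no net lateral drift.
    if cfg.spiral_kind == "arithmetic":
        state.spiral_phase = cfg.spiral_r_start / cfg.spiral_pitch
    else:
        state.spiral_phase = 0.0
    state.spiral_dir = -state.spiral_dir
    tangent = _spiral_tangent(state.spiral_phase, cfg)
    tangent = np.array([tangent[0], state.spiral_dir * tangent[1]])
    entry = state.heading + state.spiral_dir * (math.pi / 2.0)
    entry_dir = np.array([math.sin(entry), math.cos(entry)])
    state.spiral_rot = math.atan2(entry_dir[1], entry_dir[0]) \
        - math.atan2(tangent[1], tangent[0])
    state.spiral_center = state.position - _rotate(
        _mirror(spiral_point(state.spiral_phase, cfg), state.spiral_dir),
        state.spiral_rot)


def _enter_zigzag(state: AgentState, cfg: ReactiveConfig) -> None:
    state.mode = Mode.ZIGZAG
    state.mode_clock = 0.0
    state.dist_in_phase = 0.0
    state.zigzag_leg_index = 0
    state.zigzag_side = 1
    state.zigzag_axis_x = float(state.position[0])
    state.n_crossings = 0
    state.heading = math.radians(cfg.zigzag_angle_deg)


def _move_straight(state: AgentState, distance: float) -> None:
    state.position = state.position + distance * np.array(
        [math.sin(state.heading), math.cos(state.heading)]
    )


def advance(state: AgentState, cfg: ReactiveConfig, dt: float) -> AgentState:
    """Advance the agent ``dt`` seconds along its current mode's geometry.

    Mode transitions (surge exhausted, zigzag leg end, zigzag timeout) are
    handled exactly within the tick, so leg lengths and surge lengths do not
    depend on the sampling interval.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    remaining = dt
    while remaining > 1e-12:
        if state.mode is Mode.SURGE:
            state.heading = 0.0
            time_left = (cfg.surge_length - state.dist_in_phase) / cfg.speed
            step = min(remaining, time_left)
            _move_straight(state, cfg.speed * step)
            state.dist_in_phase += cfg.speed * step
            state.mode_clock += step
            remaining -= step
            if state.dist_in_phase >= cfg.surge_length - 1e-12:
                if cfg.use_zigzag:
                    _enter_zigzag(state, cfg)
                else:
                    _enter_spiral(state, cfg)
        elif state.mode is Mode.ZIGZAG:
            leg_length = cfg.zigzag_step0 * 2.0 ** state.zigzag_leg_index
            state.heading = state.zigzag_side * math.radians(cfg.zigzag_angle_deg)
            time_to_leg = (leg_length - state.dist_in_phase) / cfg.speed
            time_to_timeout = cfg.zigzag_timeout - state.mode_clock
            step = min(remaining, time_to_leg, time_to_timeout)
            before = state.position[0] - state.zigzag_axis_x
            _move_straight(state, cfg.speed * step)
            after = state.position[0] - state.zigzag_axis_x
            if before * after < 0:
                state.n_crossings += 1
            state.dist_in_phase += cfg.speed * step
            state.mode_clock += step
            remaining -= step
            if state.mode_clock >= cfg.zigzag_timeout - 1e-12:
                _enter_spiral(state, cfg)
            elif state.dist_in_phase >= leg_length - 1e-12:
                state.zigzag_leg_index += 1
                state.zigzag_side = -state.zigzag_side
                state.dist_in_phase = 0.0
        else:  # SPIRAL
            arc = cfg.speed * remaining
            new_phase = _phase_after_arc(state.spiral_phase, arc, cfg)
            new_pos = state.spiral_center + _rotate(
                _mirror(spiral_point(new_phase, cfg), state.spiral_dir),
                state.spiral_rot)
            delta = new_pos - state.position
            if float(np.hypot(*delta)) > 0:
                state.heading = math.atan2(delta[0], delta[1])
            state.position = new_pos
            state.spiral_phase = new_phase
            state.mode_clock += remaining
            remaining = 0.0
    # keep heading in (-pi, pi]
    if state.heading <= -math.pi or state.heading > math.pi:
        state.heading = math.atan2(math.sin(state.heading), math.cos(state.heading))
    return state
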