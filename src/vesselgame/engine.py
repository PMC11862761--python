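"""Deterministic, headless game mechanics.

A session wraps a generated :class:`~vesselgame.scene.Scene` and consumes
time-stamped pointer events (move / press / drag / release).  Pressing
opens a cut line at the cursor; dragging extends it, clamped so its length
never exceeds ``l_max`` (45 units by default); releasing closes the line,
increments the attempt counter and checks whether the line fully transects
the target vessel.  On success the timer freezes and later events are
ignored.

The clock is injected so tests and replays control time exactly; replaying
the same (scene, config, events) always yields an identical trial record.
"""

from __future__ import annotations

import logging
import math
import time as _time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from shapely.geometry import LineString, Point as ShapelyPoint, Polygon

from .config import RunConfig
from .errors import ConfigError, ProtocolError
from .scene import FOV_FULL, FOV_LIMITED, Point, Scene, VesselPath, count_crossings

logger = logging.getLogger(__name__)

EVENT_KINDS = ("move", "press", "drag", "release")


@dataclass(frozen=True)
class PointerEvent:
    """One pointer sample: seconds since session start, kind, position."""

    t: float
    kind: str
    position: Point

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ProtocolError(f"unknown event kind {self.kind!r}")


@dataclass
class CutLine:
    start: Point
    end: Point

    @property
    def length(self) -> float:
        return math.hypot(self.end.x - self.start.x, self.end.y - self.start.y)


@dataclass
class AttemptResult:
    success: bool
    line: CutLine
    cut_vessel_index: Optional[int]
    attempts_so_far: int


@dataclass
class TrialRecord:
    """One participant x level outcome (the trial-log CSV row)."""

    participant_id: str
    level_id: int
    fov_mode: str
    time_s: float
    attempts: int
    success: bool
    seed: int


@dataclass
class GameState:
    scene: Scene
    fov_mode: str
    fov_radius: float
    config: RunConfig
    clock: Callable[[], float]
    t0: float = 0.0
    cursor: Point = Point(0.0, 0.0)
    active_line: Optional[CutLine] = None
    attempts: int = 0
    elapsed: float = 0.0
    completed: bool = False
    revealed: list[tuple[Point, float]] = field(default_factory=list)
    results: list[AttemptResult] = field(default_factory=list)

    # -- clock-stamped convenience wrappers (interactive use) -------------
    def _stamp(self) -> float:
        return self.clock() - self.t0

    def move(self, x: float, y: float) -> None:
        apply_event(self, PointerEvent(self._stamp(), "move", Point(x, y)))

    def press(self, x: float, y: float) -> None:
        apply_event(self, PointerEvent(self._stamp(), "press", Point(x, y)))

    def drag(self, x: float, y: float) -> None:
        apply_event(self, PointerEvent(self._stamp(), "drag", Point(x, y)))

    def release(self, x: float, y: float) -> None:
        apply_event(self, PointerEvent(self._stamp(), "release", Point(x, y)))


def new_session(
    scene: Scene,
    fov_mode: str = FOV_FULL,
    fov_radius: float | None = None,
    clock: Callable[[], float] | None = None,
    config: RunConfig | None = None,
) -> GameState:
    """Start a session: attempts 0, timer running from the injected clock."""
    cfg = config or RunConfig()
    radius = cfg.fov_radius if fov_radius is None else fov_radius
    if fov_mode == FOV_LIMITED and radius <= 0:
        raise ConfigError("limited FOV requires a positive fov_radius")
    if fov_mode not in (FOV_FULL, FOV_LIMITED):
        raise ConfigError(f"unknown fov_mode {fov_mode!r}")
    clk = clock if clock is not None else _time.monotonic
    state = GameState(
        scene=scene,
        fov_mode=fov_mode,
        fov_radius=radius,
        config=cfg,
        clock=clk,
        cursor=Point(scene.width / 2.0, scene.height / 2.0),
    )
    state.t0 = clk()
    return state


def visible(state: GameState, p: Point | tuple) -> bool:
    """Is point ``p`` visible? Full FOV: always.  Limited: inside the
    spotlight circle around the cursor, or inside any revealed region."""
    if state.fov_mode == FOV_FULL:
        return True
    px, py = p
    if math.hypot(px - state.cursor.x, py - state.cursor.y) <= state.fov_radius:
        return True
    for center, r in state.revealed:
        if math.hypot(px - center.x, py - center.y) <= r:
            return True
    return False


def _clamp_line_end(start: Point, end: Point, l_max: float) -> Point:
    dx, dy = end.x - start.x, end.y - start.y
    d = math.hypot(dx, dy)
    if d <= l_max or d == 0.0:
        return end
    s = l_max / d
    return Point(start.x + dx * s, start.y + dy * s)


def is_cut(line: CutLine, vessel: VesselPath, strict_sides: bool = False) -> bool:
    """Does the line fully transect the vessel band?

    True iff both endpoints are strictly outside the vessel polygon and the
    open segment passes through the polygon interior (enters and exits).
    With ``strict_sides`` the segment must additionally cross the vessel
    centerline, excluding cuts that clip a flat end cap only.
    """
    if line.length == 0.0:
        return False
    poly = Polygon([tuple(p) for p in vessel.polygon])
    if poly.covers(ShapelyPoint(line.start)) or poly.covers(ShapelyPoint(line.end)):
        return False
    seg = LineString([tuple(line.start), tuple(line.end)])
    if not seg.relate_pattern(poly, "T********"):
        return False
    if strict_sides:
        return count_crossings([line.start, line.end], vessel.centerline) >= 1
    return True


def evaluate_release(state: GameState, line: CutLine) -> AttemptResult:
    """Judge a closed line: success iff it cuts the target vessel.

    Cutting a non-target vessel is recorded via ``cut_vessel_index`` but
    counts only as a failed attempt (no extra penalty)."""
    strict = state.config.strict_sides
    target_idx = state.scene.target_index
    cut_index: Optional[int] = None
    if is_cut(line, state.scene.vessels[target_idx], strict):
        cut_index = target_idx
    else:
        for i, v in enumerate(state.scene.vessels):
            if i != target_idx and is_cut(line, v, strict):
                cut_index = i
                break
    success = cut_index == target_idx
    return AttemptResult(
        success=success,
        line=line,
        cut_vessel_index=cut_index,
        attempts_so_far=state.attempts,
    )


def apply_event(state: GameState, e: PointerEvent) -> GameState:
    """Advance the session by one pointer event (mutates and returns state)."""
    if state.completed:
        logger.debug("event after completion ignored: %s", e)
        return state
    if e.t < state.elapsed:
        raise ProtocolError(
            f"event time {e.t} precedes current elapsed {state.elapsed}"
        )
    state.elapsed = e.t
    if e.kind in ("move", "drag"):
        state.cursor = e.position
        if e.kind == "drag":
            if state.active_line is None:
                raise ProtocolError("drag without press")
            state.active_line.end = _clamp_line_end(
                state.active_line.start, e.position, state.config.l_max
            )
    elif e.kind == "press":
        if state.active_line is not None:
            raise ProtocolError("press while a line is already active")
        state.cursor = e.position
        state.active_line = CutLine(start=e.position, end=e.position)
    elif e.kind == "release":
        if state.active_line is None:
            raise ProtocolError("release without press")
        state.cursor = e.position
        state.active_line.end = _clamp_line_end(
            state.active_line.start, e.position, state.config.l_max
        )
        line = state.active_line
        state.active_line = None
        state.attempts += 1
        result = evaluate_release(state, line)
        result.attempts_so_far = state.attempts
        state.results.append(result)
        if result.success:
            state.completed = True  # timer frozen at e.t
    return state


def replay(
    scene: Scene,
    fov_mode: str,
    events: Sequence[PointerEvent],
    fov_radius: float | None = None,
    config: RunConfig | None = None,
    participant_id: str = "replay",
) -> TrialRecord:
    """Reconstruct a full session from an event stream, deterministically.

    The stream must be time-ordered with alternating press/release; a
    malformed stream raises :class:`ProtocolError` carrying the offending
    event index.
    """
    state = new_session(scene, fov_mode, fov_radius, clock=lambda: 0.0, config=config)
    pressed = False
    last_t = 0.0
    for i, e in enumerate(events):
        if e.t < last_t:
            raise ProtocolError(f"events out of order at index {i}", index=i)
        last_t = e.t
        if e.kind == "press":
            if pressed:
                raise ProtocolError(f"press without release at index {i}", index=i)
            pressed = True
        elif e.kind == "release":
            if not pressed:
                raise ProtocolError(f"release without press at index {i}", index=i)
            pressed = False
        elif e.kind == "drag" and not pressed:
            raise ProtocolError(f"drag without press at index {i}", index=i)
        apply_event(state, e)
    return TrialRecord(
        participant_id=participant_id,
        level_id=scene.level_id,
        fov_mode=fov_mode,
        time_s=round(state.elapsed, config.time_decimals if config else 3),
        attempts=state.attempts,
        success=state.completed,
        seed=scene.seed,
    )


def reveal(state: GameState, p: Point | tuple) -> GameState:
    """Paint mode: permanently reveal a circular region of the scene at p."""
    if not state.config.paint_mode:
        raise ConfigError("reveal requires paint_mode to be enabled")
    px, py = p
    state.revealed.append((Point(px, py), state.fov_radius))
    return state
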