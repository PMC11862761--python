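"""Procedural generation of vessel scenes.

A scene is a fixed-size playfield crossed horizontally by one to three
"vessels": wavy bands obtained by stroking a smooth centerline with a
constant width.  Every vessel spans the full window width.  Exactly one
vessel is the *target*; its two centerline endpoints carry black circular
markers, all other endpoints carry non-black markers of the same radius.

Level structure (id -> vessels, intertwined, field of view):

    1 -> 1, plain,       full
    2 -> 2, plain,       full
    3 -> 1, plain,       limited
    4 -> 2, intertwined, full
    5 -> 2, intertwined, limited
    6 -> 3, intertwined, full
    7 -> 3, intertwined, limited

Levels 4/5 and 6/7 differ only in the field of view, which is what makes
the matched-pair comparison in :mod:`vesselgame.stats` possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import LineString, Polygon

from .config import RunConfig
from .errors import DegenerateGeometryError, GenerationError, InvalidLevelError

FOV_FULL = "full"
FOV_LIMITED = "limited"

#: level_id -> (n_vessels, intertwined, fov_mode)
LEVEL_TABLE: dict[int, tuple[int, bool, str]] = {
    1: (1, False, FOV_FULL),
    2: (2, False, FOV_FULL),
    3: (1, False, FOV_LIMITED),
    4: (2, True, FOV_FULL),
    5: (2, True, FOV_LIMITED),
    6: (3, True, FOV_FULL),
    7: (3, True, FOV_LIMITED),
}


class Point(NamedTuple):
    """Scene coordinate: origin top-left, x rightward, y downward."""

    x: float
    y: float


@dataclass(frozen=True)
class LevelSpec:
    level_id: int
    n_vessels: int
    intertwined: bool
    fov_mode: str


@dataclass
class VesselPath:
    centerline: list[Point]
    width: float
    polygon: list[Point]
    is_target: bool = False


@dataclass
class Marker:
    center: Point
    radius: float
    is_black: bool


@dataclass
class Scene:
    width: float
    height: float
    level_id: int
    seed: int
    vessels: list[VesselPath]
    markers: list[Marker]
    target_index: int
    palette: tuple[tuple[int, int, int], tuple[int, int, int]] = (
        (205, 92, 92),
        (178, 34, 34),
    )

    @property
    def target(self) -> VesselPath:
        return self.vessels[self.target_index]


def make_level_spec(level_id: int) -> LevelSpec:
    """Return the level definition for ``level_id`` (1-7)."""
    try:
        n, inter, fov = LEVEL_TABLE[level_id]
    except (KeyError, TypeError):
        raise InvalidLevelError(f"level_id must be an integer in 1..7, got {level_id!r}")
    return LevelSpec(level_id=level_id, n_vessels=n, intertwined=inter, fov_mode=fov)


def generate_centerline(
    rng: np.random.Generator | int,
    width: float,
    height: float,
    n_waypoints: int = 6,
    y_band: tuple[float, float] | None = None,
    n_samples: int = 100,
) -> list[Point]:
    """Generate a smooth left-to-right centerline across the window.

    ``n_waypoints`` waypoints are placed at equally spaced x positions with
    y drawn uniformly inside ``y_band`` (default: an 8% vertical margin),
    then joined by a natural cubic spline sampled at ``n_samples`` points.
    The first point has x == 0 and the last x == width, so the vessel spans
    the window.  Sampled y values are clipped back into the band.

    Passing a collapsed band (lo == hi) yields a straight horizontal line.
    Same seed, same arguments -> identical output.
    """
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    if n_waypoints < 2:
        raise ValueError("n_waypoints must be >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    margin = 0.08 * height
    lo, hi = y_band if y_band is not None else (margin, height - margin)
    xs = np.linspace(0.0, width, n_waypoints)
    ys = rng.uniform(lo, hi, size=n_waypoints) if hi > lo else np.full(n_waypoints, lo)
    spline = CubicSpline(xs, ys, bc_type="natural")
    sx = np.linspace(0.0, width, n_samples)
    sy = np.clip(spline(sx), lo, hi)
    sx[0], sx[-1] = 0.0, width  # exact endpoints
    return [Point(float(x), float(y)) for x, y in zip(sx, sy)]


def stroke_polygon(centerline: Sequence[Point | tuple], width: float) -> list[Point]:
    """Stroke a centerline into its outline polygon.

    The result is the band offset by ``width/2`` to each side with flat end
    caps, returned as a closed simple ring (closing vertex omitted).
    """
    if len(centerline) < 2:
        raise DegenerateGeometryError("centerline needs at least 2 points")
    if width <= 0:
        raise ValueError("width must be positive")
    pts = [tuple(p) for p in centerline]
    for a, b in zip(pts, pts[1:]):
        if a == b:
            raise DegenerateGeometryError(f"consecutive duplicate centerline point {a}")
    poly = LineString(pts).buffer(width / 2.0, cap_style="flat", join_style="round")
    if not isinstance(poly, Polygon) or not poly.is_valid or poly.interiors:
        raise DegenerateGeometryError("stroked outline is not a simple polygon")
    ring = list(poly.exterior.coords)[:-1]
    return [Point(float(x), float(y)) for x, y in ring]


def _cross(ox, oy, ax, ay, bx, by):
    return (ax - ox) * (by - oy) - (ay - oy) * (bx - ox)


def count_crossings(a: Sequence[Point | tuple], b: Sequence[Point | tuple]) -> int:
    """Count transversal intersection points between two polylines.

    Proper (strictly crossing) segment intersections only; touching or
    collinear overlaps do not count.  Symmetric in its arguments.
    Vectorized over all segment pairs.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both polylines need at least 2 points")
    pa = np.asarray([tuple(p) for p in a], dtype=float)
    pb = np.asarray([tuple(p) for p in b], dtype=float)
    a1, a2 = pa[:-1], pa[1:]  # (n, 2)
    b1, b2 = pb[:-1], pb[1:]  # (m, 2)
    ax, ay = a1[:, None, 0], a1[:, None, 1]
    bx, by = a2[:, None, 0], a2[:, None, 1]
    cx, cy = b1[None, :, 0], b1[None, :, 1]
    dx, dy = b2[None, :, 0], b2[None, :, 1]
    d1 = _cross(ax, ay, bx, by, cx, cy)
    d2 = _cross(ax, ay, bx, by, dx, dy)
    d3 = _cross(cx, cy, dx, dy, ax, ay)
    d4 = _cross(cx, cy, dx, dy, bx, by)
    proper = (
        ((d1 > 0) != (d2 > 0))
        & ((d3 > 0) != (d4 > 0))
        & (d1 != 0) & (d2 != 0) & (d3 != 0) & (d4 != 0)
    )
    return int(proper.sum())


def _disjoint_bands(height: float, n: int, margin: float) -> list[tuple[float, float]]:
    usable = height - 2 * margin
    h = usable / n
    pad = 0.15 * h
    return [
        (margin + i * h + pad, margin + (i + 1) * h - pad)
        for i in range(n)
    ]


def _intertwined_centerlines(
    rng: np.random.Generator,
    n_vessels: int,
    width: float,
    height: float,
    n_waypoints: int,
    n_samples: int,
) -> list[list[Point]]:
    """Centerlines whose pairwise vertical order flips at every waypoint.

    Alternating the rank order of the waypoint y values forces every pair
    of splines to cross between consecutive waypoints, which makes the
    k_min-crossings constraint easy to satisfy by rejection.
    """
    margin = 0.08 * height
    lo, hi = margin, height - margin
    xs = np.linspace(0.0, width, n_waypoints)
    # one column of sorted y values per waypoint, order reversed alternately
    ys = np.empty((n_waypoints, n_vessels))
    for k in range(n_waypoints):
        col = np.sort(rng.uniform(lo, hi, size=n_vessels))
        ys[k] = col if k % 2 == 0 else col[::-1]
    lines = []
    sx = np.linspace(0.0, width, n_samples)
    sx[0], sx[-1] = 0.0, width
    for v in range(n_vessels):
        spline = CubicSpline(xs, ys[:, v], bc_type="natural")
        sy = np.clip(spline(sx), lo, hi)
        lines.append([Point(float(x), float(y)) for x, y in zip(sx, sy)])
    return lines


def generate_scene(
    spec: LevelSpec,
    width: float | None = None,
    height: float | None = None,
    seed: int = 0,
    config: RunConfig | None = None,
) -> Scene:
    """Generate a reproducible scene satisfying the level's constraints.

    Intertwined levels require every pair of centerlines to cross at least
    ``config.k_min_crossings`` times; plain levels must have zero crossings.
    Generation rejects and redraws until the constraints hold, up to
    ``config.retry_cap`` attempts.
    """
    cfg = config or RunConfig()
    w = float(width if width is not None else cfg.scene_width)
    h = float(height if height is not None else cfg.scene_height)
    rng = np.random.default_rng(seed)
    n = spec.n_vessels
    for _attempt in range(cfg.retry_cap):
        try:
            if spec.intertwined and n > 1:
                centerlines = _intertwined_centerlines(
                    rng, n, w, h, cfg.n_waypoints, n_samples=100
                )
            else:
                bands = _disjoint_bands(h, n, 0.08 * h)
                order = rng.permutation(n)
                centerlines = [None] * n
                for slot, v in enumerate(order):
                    centerlines[v] = generate_centerline(
                        rng, w, h, cfg.n_waypoints, y_band=bands[slot]
                    )
            # constraint check
            ok = True
            for i in range(n):
                for j in range(i + 1, n):
                    k = count_crossings(centerlines[i], centerlines[j])
                    if spec.intertwined and k < cfg.k_min_crossings:
                        ok = False
                    if not spec.intertwined and k != 0:
                        ok = False
            if not ok:
                continue
            polygons = [stroke_polygon(c, cfg.vessel_width) for c in centerlines]
        except DegenerateGeometryError:
            continue
        target_index = int(rng.integers(n))
        vessels = [
            VesselPath(
                centerline=c,
                width=cfg.vessel_width,
                polygon=p,
                is_target=(i == target_index),
            )
            for i, (c, p) in enumerate(zip(centerlines, polygons))
        ]
        markers = []
        for i, v in enumerate(vessels):
            for end in (v.centerline[0], v.centerline[-1]):
                markers.append(
                    Marker(center=end, radius=cfg.marker_radius,
                           is_black=(i == target_index))
                )
        return Scene(
            width=w,
            height=h,
            level_id=spec.level_id,
            seed=seed,
            vessels=vessels,
            markers=markers,
            target_index=target_index,
            palette=cfg.palette,
        )
    raise GenerationError(
        f"could not satisfy constraints for level {spec.level_id} "
        f"within {cfg.retry_cap} attempts (k_min={cfg.k_min_crossings})"
    )
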