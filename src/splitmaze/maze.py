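"""Canonical maze geometry: seven octagonal enclosures linked by seven alleys.

The apparatus is a double-Y: a start box feeds a central stem to a first
choice point, two diagonal stems lead to left/right choice points, and from
each of those two diagonal alleys reach a goal box.  Routes 2 and 3 (from the
left and right choice points respectively) converge on the single Centre Goal
Box, which is what makes the route-versus-goal comparison possible.

Coordinates are in cm, origin at the start-box centre, y increasing toward
the goal boxes.  Enclosures are regular octagons with a 25 cm flat-to-flat
width; alleys are 20 cm x 10 cm rectangles spanning exactly the gap between
two octagon facets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

__all__ = [
    "MazeLayout",
    "build_maze_layout",
    "ROUTE_GOAL",
    "GOALS",
    "SECTOR_NAMES",
    "SCORED_SECTORS",
]

#: goal box reached by each route (routes 2 and 3 share the Centre box)
ROUTE_GOAL = {1: "left", 2: "centre", 3: "centre", 4: "right"}
GOALS = ("left", "centre", "right")

#: canonical sector order; doubles as the half-open assignment priority
SECTOR_NAMES = (
    "start_box",
    "central_stem",
    "first_choice",
    "left_stem",
    "right_stem",
    "left_choice",
    "right_choice",
    "route1_alley",
    "route2_alley",
    "route3_alley",
    "route4_alley",
    "left_goal_box",
    "centre_goal_box",
    "right_goal_box",
)

#: sectors scored for differential firing
SCORED_SECTORS = ("start_box", "central_stem", "left_stem", "right_stem")

_SQ2 = np.sqrt(2.0) / 2.0


def _octagon(cx: float, cy: float, width: float) -> Polygon:
    """Regular octagon with flat-to-flat width ``width``, facets every 45 deg."""
    r = (width / 2.0) / np.cos(np.pi / 8.0)
    ang = np.pi / 8.0 + np.arange(8) * np.pi / 4.0
    return Polygon(np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)]))


def _alley(a: np.ndarray, b: np.ndarray, apothem: float, length: float, width: float) -> Polygon:
    """Rectangle of given length/width spanning the gap between two octagons
    centred at ``a`` and ``b`` (facet-to-facet along the connecting axis)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    u = (b - a) / np.linalg.norm(b - a)
    n = np.array([-u[1], u[0]])
    p0 = a + apothem * u
    p1 = p0 + length * u
    h = width / 2.0
    return Polygon([p0 + h * n, p1 + h * n, p1 - h * n, p0 - h * n])


@dataclass(frozen=True)
class MazeLayout:
    """Named sector polygons, distance ranks, and per-route centerlines."""

    sectors: dict  # name -> shapely Polygon
    sector_order: dict  # name -> integer distance rank from start box
    route_paths: dict  # route id -> (sector name tuple, centerline (k,2) array)
    box_width: float = 25.0
    alley_length: float = 20.0
    alley_width: float = 10.0

    @property
    def names(self) -> tuple:
        return tuple(self.sectors)

    @property
    def union(self):
        return unary_union(list(self.sectors.values()))

    def bounding_box(self) -> tuple:
        return self.union.bounds

    def assign_sectors(self, x, y):
        """Sector index (into ``SECTOR_NAMES``) of each point, -1 outside.

        Boundary points go to the earliest sector in canonical order (the
        half-open convention used for both position samples and spikes).
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        out = np.full(x.shape, -1, dtype=np.int64)
        # iterate last-to-first so the earliest (highest-priority) sector
        # writes last and wins on shared boundaries
        for i in range(len(self.names) - 1, -1, -1):
            poly = self.sectors[self.names[i]]
            out[shapely.intersects_xy(poly, x, y)] = i
        return out

    def contains(self, x, y):
        """True where (x, y) lies in the union of all sectors."""
        return self.assign_sectors(x, y) >= 0

    def goal_box_sector(self, route: int) -> str:
        return f"{ROUTE_GOAL[route]}_goal_box"


def build_maze_layout(
    box_width: float = 25.0,
    alley_length: float = 20.0,
    alley_width: float = 10.0,
) -> MazeLayout:
    """Construct the canonical 14-sector layout.

    Parameters override the apparatus dimensions (cm); all must be positive.
    """
    for label, v in (
        ("box_width", box_width),
        ("alley_length", alley_length),
        ("alley_width", alley_width),
    ):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{label} must be positive, got {v!r}")

    apo = box_width / 2.0
    step = box_width + alley_length  # centre-to-centre spacing along any axis

    start = np.array([0.0, 0.0])
    cp1 = start + step * np.array([0.0, 1.0])
    upleft = step * np.array([-_SQ2, _SQ2])
    upright = step * np.array([_SQ2, _SQ2])
    left_cp = cp1 + upleft
    right_cp = cp1 + upright
    left_goal = left_cp + upleft
    centre_goal = left_cp + upright  # == right_cp + upleft
    right_goal = right_cp + upright

    centres = {
        "start_box": start,
        "first_choice": cp1,
        "left_choice": left_cp,
        "right_choice": right_cp,
        "left_goal_box": left_goal,
        "centre_goal_box": centre_goal,
        "right_goal_box": right_goal,
    }

    sectors = {name: _octagon(*centres[name], box_width) for name in centres}
    alley_pairs = {
        "central_stem": (start, cp1),
        "left_stem": (cp1, left_cp),
        "right_stem": (cp1, right_cp),
        "route1_alley": (left_cp, left_goal),
        "route2_alley": (left_cp, centre_goal),
        "route3_alley": (right_cp, centre_goal),
        "route4_alley": (right_cp, right_goal),
    }
    for name, (a, b) in alley_pairs.items():
        sectors[name] = _alley(a, b, apo, alley_length, alley_width)
    sectors = {name: sectors[name] for name in SECTOR_NAMES}

    sector_order = {
        "start_box": 0,
        "central_stem": 1,
        "first_choice": 2,
        "left_stem": 3,
        "right_stem": 3,
        "left_choice": 4,
        "right_choice": 4,
        "route1_alley": 5,
        "route2_alley": 5,
        "route3_alley": 5,
        "route4_alley": 5,
        "left_goal_box": 6,
        "centre_goal_box": 6,
        "right_goal_box": 6,
    }

    common = ("start_box", "central_stem", "first_choice")
    route_paths = {
        1: (
            common + ("left_stem", "left_choice", "route1_alley", "left_goal_box"),
            np.array([start, cp1, left_cp, left_goal]),
        ),
        2: (
            common + ("left_stem", "left_choice", "route2_alley", "centre_goal_box"),
            np.array([start, cp1, left_cp, centre_goal]),
        ),
        3: (
            common + ("right_stem", "right_choice", "route3_alley", "centre_goal_box"),
            np.array([start, cp1, right_cp, centre_goal]),
        ),
        4: (
            common + ("right_stem", "right_choice", "route4_alley", "right_goal_box"),
            np.array([start, cp1, right_cp, right_goal]),
        ),
    }

    return MazeLayout(
        sectors=sectors,
        sector_order=sector_order,
        route_paths=route_paths,
        box_width=box_width,
        alley_length=alley_length,
        alley_width=alley_width,
    )
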