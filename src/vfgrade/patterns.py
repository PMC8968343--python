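"""Perimetry test-pattern geometry.

A :class:`TestPattern` holds the test-point coordinates of a perimetry grid in
degrees of visual angle, in right-eye convention: x > 0 is temporal (the blind
spot sits near (+15, +/-3)), y > 0 is superior. Three grids are shipped as data
fixtures:

* ``HFA24_2`` -- Humphrey 24-2, 54 points on a 6 deg lattice offset 3 deg from
  the meridians, with the nasal extension points at x = -27 deg.
* ``HFA30_2`` -- Humphrey 30-2, 76 points, a superset of the 24-2 grid.
* ``G1`` -- an Octopus G1-like grid: 59 irregularly spaced points, denser
  centrally, with a foveal point. The exact G1 coordinates are instrument
  constants not in the public domain; the shipped fixture is a synthetic
  reconstruction matching the pattern's qualitative geometry (see
  ``data/grid_g1.csv``).

Adjacency between points is the 8-neighbourhood for the rectangular Humphrey
lattices and the Delaunay triangulation (edges longer than 10 deg pruned) for
the irregular G1 grid; it drives the connected-component analysis of defects.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources

import numpy as np


class PatternId(str, Enum):
    """Identifier of a supported perimetry test pattern."""

    G1 = "G1"
    HFA24_2 = "HFA24_2"
    HFA30_2 = "HFA30_2"


_FIXTURES = {
    PatternId.G1: "grid_g1.csv",
    PatternId.HFA24_2: "grid_hfa24_2.csv",
    PatternId.HFA30_2: "grid_hfa30_2.csv",
}

EXPECTED_POINT_COUNTS = {
    PatternId.G1: 59,
    PatternId.HFA24_2: 54,
    PatternId.HFA30_2: 76,
}

#: neighbour cut-off for the 6-deg Humphrey lattices (covers straight and
#: diagonal neighbours at 6 and ~8.49 deg, excludes second neighbours at 12)
_HFA_NEIGHBOR_MAX = 9.0
#: Delaunay edges longer than this are pruned on irregular grids
_DELAUNAY_MAX_EDGE = 10.0


@dataclass(frozen=True)
class TestPattern:
    """Geometry of one perimetry grid.

    Attributes
    ----------
    pattern_id : PatternId
    points : (k, 2) float array of (x, y) in degrees, canonical order
        (superior-to-inferior rows, nasal-to-temporal within a row).
    blind_spot : int array of point indices at the physiologic blind spot.
    adjacency : frozenset of (i, j) index pairs with i < j (symmetric relation).
    """

    pattern_id: PatternId
    points: np.ndarray
    blind_spot: np.ndarray
    adjacency: frozenset = field(repr=False)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def non_blind_spot(self) -> np.ndarray:
        mask = np.ones(self.n_points, dtype=bool)
        mask[self.blind_spot] = False
        return np.flatnonzero(mask)

    def neighbors(self, i: int) -> list[int]:
        out = [b for a, b in self.adjacency if a == i]
        out += [a for a, b in self.adjacency if b == i]
        return sorted(out)

    def adjacency_lists(self) -> list[list[int]]:
        """Neighbour lists for all points (symmetric, irreflexive)."""
        lists: list[list[int]] = [[] for _ in range(self.n_points)]
        for a, b in self.adjacency:
            lists[a].append(b)
            lists[b].append(a)
        return [sorted(l) for l in lists]

    def eccentricity(self) -> np.ndarray:
        return np.hypot(self.points[:, 0], self.points[:, 1])

    def index_at(self, x: float, y: float, tol: float = 1e-6) -> int:
        """Index of the point at (x, y); raises KeyError if absent."""
        d = np.hypot(self.points[:, 0] - x, self.points[:, 1] - y)
        i = int(np.argmin(d))
        if d[i] > tol:
            raise KeyError(f"no test point at ({x}, {y})")
        return i


def _read_fixture(pattern_id: PatternId) -> tuple[np.ndarray, np.ndarray]:
    name = _FIXTURES[pattern_id]
    with resources.files("vfgrade.data").joinpath(name).open() as f:
        rows = list(csv.DictReader(f))
    pts = np.array([[float(r["x_deg"]), float(r["y_deg"])] for r in rows])
    bs = np.array([i for i, r in enumerate(rows) if int(r["is_blind_spot"])],
                  dtype=int)
    return pts, bs


def _lattice_adjacency(points: np.ndarray) -> frozenset:
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    i, j = np.nonzero((d > 0) & (d <= _HFA_NEIGHBOR_MAX))
    return frozenset((int(a), int(b)) for a, b in zip(i, j) if a < b)

def _delaunay_adjacency(points: np.ndarray) -> frozenset:
    from scipy.spatial import Delaunay

    tri = Delaunay(points)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            if np.linalg.norm(points[i] - points[j]) <= _DELAUNAY_MAX_EDGE:
                edges.add((min(i, j), max(i, j)))
    return frozenset(edges)


@lru_cache(maxsize=None)
def get_pattern(pattern_id: PatternId | str) -> TestPattern:
    """Load a grid fixture and derive its adjacency relation."""
    pattern_id = PatternId(pattern_id)
    points, blind_spot = _read_fixture(pattern_id)
    if len(points) != EXPECTED_POINT_COUNTS[pattern_id]:
        raise ValueError(
            f"{pattern_id.value} fixture has {len(points)} points, expected "
            f"{EXPECTED_POINT_COUNTS[pattern_id]}")
    if pattern_id is PatternId.G1:
        adjacency = _delaunay_adjacency(points)
    else:
        adjacency = _lattice_adjacency(points)
    points.setflags(write=False)
    blind_spot.setflags(write=False)
    return TestPattern(pattern_id, points, blind_spot, adjacency)
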