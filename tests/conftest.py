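import numpy as np
import pytest

from sprouttrack.graph import SkeletonGraph


def make_graph(coords: dict, edges: list) -> SkeletonGraph:
    """Straight-segment graph from node coordinates and edge pairs."""
    g = SkeletonGraph()
    for nid, (x, y) in coords.items():
        g.add_node(x, y, node_id=nid)
    for a, b in edges:
        g.add_segment(a, b)
    g.relabel_roles(preserve_base=False)
    return g


def tube_mask(shape: tuple[int, int], points, radius: float) -> np.ndarray:
    """Binary tube swept along a polyline (exact distance rasterization)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    best = np.full((h, w), np.inf)
    pts = np.asarray(points, dtype=float)
    for p0, p1 in zip(pts[:-1], pts[1:]):
        d = p1 - p0
        denom = float(d @ d)
        t = np.clip(((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / denom, 0, 1) if denom else 0.0
        best = np.minimum(best, np.hypot(xx - (p0[0] + t * d[0]), yy - (p0[1] + t * d[1])))
    return best <= radius


@pytest.fixture
def two_sprout_graph():
    """Geometric realization of the printed two-sprout example: one sprout
    with nested branching, a second single-branch sprout, and the
    near-horizontal artificial connector (2-3) still present."""
    g = make_graph(
        {1: (100, 390), 2: (102, 375), 3: (200, 385), 4: (105, 300),
         5: (205, 330), 6: (80, 240), 7: (130, 250), 8: (115, 190), 9: (160, 200)},
        [(1, 2), (2, 4), (4, 6), (4, 7), (7, 8), (7, 9), (3, 5), (2, 3)],
    )
    return g


@pytest.fixture
def two_day_frames():
    """Geometric realization of the printed two-day association example:
    day 9 routes [1 2 3], [1 2 4]; day 10 routes [1 2 3], [1 2 4 5],
    [1 2 4 6] with node 4 newly a branch node and 5 the straight
    continuation of segment [2 4]."""
    day9 = make_graph(
        {1: (100, 380), 2: (100, 330), 3: (60, 260), 4: (130, 270)},
        [(1, 2), (2, 3), (2, 4)],
    )
    day10 = make_graph(
        {1: (100, 380), 2: (100, 330), 3: (50, 230), 4: (130, 270),
         5: (150, 200), 6: (170, 250)},
        [(1, 2), (2, 3), (2, 4), (4, 5), (4, 6)],
    )
    return day9, day10
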