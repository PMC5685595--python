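"""Base-node determination and branch-route enumeration.

A *base node* is where a sprout starts, nearest the endothelial monolayer;
all branches originating from the same tip cell that left the monolayer
share one base node and together form a *sprout*.  Two scenarios occur in
segmented images: (1) all branches belong to one sprout, and the node
nearest the monolayer is the base; (2) two sprouts are spuriously joined
by a near-horizontal artificial segment left over from the cell-gel
interface — that connector must be detected (by its small rise/run ratio)
and removed, yielding two base nodes.

After base determination, one branch route is enumerated per reachable
(base, end-node) pair via arc-length-weighted shortest paths, and simple
per-route morphometrics (length, mean width) are computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph import ROLE_BASE, ROLE_BRANCH, ROLE_END, ROLE_JUNCTION, SkeletonGraph

logger = logging.getLogger(__name__)


@dataclass
class BranchingConfig:
    """tau: rise/run ratio below which a segment counts as an artificial
    near-horizontal connector (0.5 is about 27 degrees from horizontal);
    d_base: how close a branch node must be to the monolayer-nearest node
    to trigger the two-sprout check."""

    tau: float = 0.5
    d_base: float = 20.0

    def __post_init__(self):
        if self.tau <= 0 or self.d_base <= 0:
            raise ValueError("tau and d_base must be positive")


@dataclass
class BranchRoute:
    """An ordered base-to-end node path with its geometry."""

    nodes: list[int]
    polyline: np.ndarray
    length: float
    mean_radius: float
    sprout_id: int = 0
    node_positions: np.ndarray | None = None   # (len(nodes), 2), same order

    @property
    def base(self) -> int:
        return self.nodes[0]

    @property
    def end(self) -> int:
        return self.nodes[-1]

    @property
    def mean_width(self) -> float:
        return 2.0 * self.mean_radius


@dataclass
class Sprout:
    """All routes sharing one base node."""

    base_node: int
    route_indices: list[int] = field(default_factory=list)
    mean_x: float = 0.0


def rise_run_ratio(node_m, node_n) -> float:
    """|yN - yM| / |xN - xM|; +inf for a vertical pair (never artificial)."""
    dx = abs(node_n.x - node_m.x)
    dy = abs(node_n.y - node_m.y)
    return float("inf") if dx == 0 else dy / dx


def _nearest_monolayer_node(graph: SkeletonGraph, ids) -> int:
    # monolayer lies at the bottom edge: nearest = max y, ties to smaller x
    return max(ids, key=lambda nid: (graph.nodes[nid].y, -graph.nodes[nid].x))


def _segment_path_between(graph: SkeletonGraph, a: int, b: int) -> list[int]:
    """Segment ids on the (junction-free) direct connection a..b, passing
    only through junction nodes."""
    g = graph.to_networkx()
    try:
        path = nx.shortest_path(g, a, b, weight="length")
    except nx.NetworkXNoPath:
        return []
    if any(graph.nodes[n].role not in (ROLE_JUNCTION,) for n in path[1:-1]):
        return []
    return [g.edges[u, v]["segment_id"] for u, v in zip(path, path[1:])]


def determine_base_nodes(
    graph: SkeletonGraph, cfg: BranchingConfig | None = None
) -> tuple[list[int], list[int]]:
    """Find base nodes and remove artificial inter-sprout connectors.

    Applied per connected component.  The node A nearest the monolayer is
    examined: if it is an end node with a branch node B within ``d_base``,
    the two other neighbours C, D of B are tested with the rise/run ratio —
    a neighbour whose segment to B is near-horizontal (ratio < tau, strict)
    marks an artificial connector, which is removed, and that neighbour
    becomes the second base node.  If A is a junction node the same test
    runs on A's own two neighbours.  Ties at exactly tau count as genuine
    vessel (Scenario 1).  Mutates ``graph`` (connector removal + role
    relabeling); returns (base node ids, removed segment ids).
    """
    cfg = cfg or BranchingConfig()
    if graph.n_nodes == 0:
        raise ValueError("empty graph")

    bases: list[int] = []
    removed: list[int] = []

    for comp in sorted(graph.connected_components(), key=min):
        a = _nearest_monolayer_node(graph, comp)
        node_a = graph.nodes[a]
        role_a = node_a.role if node_a.role != ROLE_BASE else (
            ROLE_END if graph.degree(a) <= 1 else (ROLE_JUNCTION if graph.degree(a) == 2 else ROLE_BRANCH)
        )

        if role_a == ROLE_BRANCH:
            # not covered by the base-determination procedure; treat as the base
            logger.info("monolayer-nearest node %d is a branch node; taking it as base", a)
            node_a.role = ROLE_BASE
            bases.append(a)
            continue

        if role_a == ROLE_END:
            near_branch = [
                nid for nid in comp
                if graph.nodes[nid].role == ROLE_BRANCH
                and np.hypot(graph.nodes[nid].x - node_a.x, graph.nodes[nid].y - node_a.y) <= cfg.d_base
            ]
            if not near_branch:
                node_a.role = ROLE_BASE                      # Scenario 1
                bases.append(a)
                continue
            b = min(
                near_branch,
                key=lambda nid: np.hypot(graph.nodes[nid].x - node_a.x, graph.nodes[nid].y - node_a.y),
            )
            others = [n for n in graph.neighbors(b) if n != a]
        else:  # junction
            b = a
            others = [n for n in graph.neighbors(a) if n != a]

        node_b = graph.nodes[b]
        artificial = [n for n in others if rise_run_ratio(node_b, graph.nodes[n]) < cfg.tau]
        genuine = [n for n in others if n not in artificial]

        if not artificial or not genuine:
            # all-steep (Scenario 1) or all-flat (ambiguous: keep one sprout)
            node_a.role = ROLE_BASE
            bases.append(a)
            continue

        node_a.role = ROLE_BASE
        bases.append(a)
        for n in sorted(artificial):
            for sid in _segment_path_between(graph, b, n):
                if sid in graph.segments:
                    graph.remove_segment(sid)
                    removed.append(sid)
            graph.nodes[n].role = ROLE_BASE
            bases.append(n)

    graph.relabel_roles(preserve_base=True)
    graph.drop_orphans()
    return sorted(bases), removed


def enumerate_branch_routes(graph: SkeletonGraph, base_nodes: list[int]) -> list[BranchRoute]:
    """One route per (base, reachable end node), as arc-length shortest paths.

    Pruned sprout graphs are trees, so any positive edge weighting yields
    the same node sequences; arc length is used for the recorded lengths.
    """
    g = graph.to_networkx()
    routes: list[BranchRoute] = []
    reached_ends: set[int] = set()

    for base in sorted(base_nodes):
        if base not in g:
            continue
        lengths, paths = nx.single_source_dijkstra(g, base, weight="length")
        comp_ends = [
            nid for nid in paths
            if graph.nodes[nid].role == ROLE_END and nid != base
        ]
        for end in sorted(comp_ends):
            nodes = paths[end]
            if any(graph.nodes[n].role == ROLE_BASE for n in nodes[1:]):
                continue  # never route through another sprout's base
            poly_parts = []
            radii_parts = []
            for u, v in zip(nodes, nodes[1:]):
                seg = graph.segments[g.edges[u, v]["segment_id"]]
                pts = seg.polyline if seg.node_a == u else seg.polyline[::-1]
                poly_parts.append(pts)
                radii_parts.append(seg.radii)
            poly = np.vstack(poly_parts)
            radii = np.concatenate([r for r in radii_parts if len(r)]) if any(
                len(r) for r in radii_parts
            ) else np.empty(0)
            routes.append(
                BranchRoute(
                    nodes=list(nodes),
                    polyline=poly,
                    length=float(lengths[end]),
                    mean_radius=float(radii.mean()) if len(radii) else float("nan"),
                    node_positions=np.array(
                        [[graph.nodes[n].x, graph.nodes[n].y] for n in nodes], dtype=float
                    ),
                )
            )
            reached_ends.add(end)

    orphans = set(graph.nodes_with_role(ROLE_END)) - reached_ends
    if orphans:
        warnings.warn(f"end nodes unreachable from any base: {sorted(orphans)}", stacklevel=2)

    # group into sprouts and tag sprout ids by base-x order
    sprouts = group_sprouts(routes)
    for sid, sp in enumerate(sprouts, start=1):
        for ri in sp.route_indices:
            routes[ri].sprout_id = sid
    return routes


def group_sprouts(routes: list[BranchRoute]) -> list[Sprout]:
    """Group routes by shared base node; sprouts ordered by mean x."""
    by_base: dict[int, list[int]] = {}
    for i, r in enumerate(routes):
        by_base.setdefault(r.base, []).append(i)
    sprouts = []
    for base, idxs in by_base.items():
        xs = np.concatenate([routes[i].polyline[:, 0] for i in idxs])
        sprouts.append(Sprout(base_node=base, route_indices=idxs, mean_x=float(xs.mean())))
    sprouts.sort(key=lambda s: s.mean_x)
    return sprouts


def compute_branch_metrics(route: BranchRoute) -> dict:
    """Length, mean width and node count of one route."""
    return {
        "length_px": route.length,
        "mean_width_px": route.mean_width,
        "mean_radius_px": route.mean_radius,
        "n_nodes": len(route.nodes),
    }


def routes_to_json(routes: list[BranchRoute], path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "nodes": [int(n) for n in r.nodes],
                    "polyline": np.asarray(r.polyline).tolist(),
                    "length_px": r.length,
                    "mean_radius_px": r.mean_radius,
                    "sprout_id": r.sprout_id,
                    "node_positions": None if r.node_positions is None else np.asarray(r.node_positions).tolist(),
                }
                for r in routes
            ],
            fh,
            indent=1,
        )


def routes_from_json(path) -> list[BranchRoute]:
    import json

    with open(path) as fh:
        raw = json.load(fh)
    return [
        BranchRoute(
            nodes=list(r["nodes"]),
            polyline=np.asarray(r["polyline"], dtype=float),
            length=float(r["length_px"]),
            mean_radius=float(r["mean_radius_px"]),
            sprout_id=int(r.get("sprout_id", 0)),
            node_positions=None if r.get("node_positions") is None else np.asarray(r["node_positions"], dtype=float),
        )
        for r in raw
    ]


def routes_table(routes: list[BranchRoute], frame: int | None = None) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(routes, start=1):
        rows.append({
            "branch": i,
            "sprout": r.sprout_id,
            "route": " ".join(map(str, r.nodes)),
            "length_px": round(r.length, 2),
            "width_px": round(r.mean_width, 2),
        })
    df = pd.DataFrame(rows)
    if frame is not None:
        df.insert(0, "frame", frame)
    return df
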