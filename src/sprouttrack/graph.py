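"""Skeleton graph container shared by every pipeline stage.

A vessel skeleton is represented as a graph of *nodes* (points where the
centerline starts, ends, or branches) joined by *segments* (ordered pixel
polylines with radii sampled along them).  Node roles follow the standard
medial-axis bookkeeping for sprouting vessels:

``end``
    degree 1 — a free tip of the skeleton.
``junction``
    degree 2 — a pass-through node (typically left behind when a former
    branch node loses a segment to pruning).
``branch``
    degree >= 3 — a true branching point of the vessel.
``base``
    the node a sprout starts from, nearest the endothelial monolayer.

Geometry convention used throughout the package: images are indexed
``[row, col]``; all graph coordinates are ``(x, y)`` with ``x = col`` and
``y = row``, 0-based.  The monolayer lies along the *bottom* image edge, so
"nearest to the monolayer" means largest ``y``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

ROLE_END = "end"
ROLE_JUNCTION = "junction"
ROLE_BRANCH = "branch"
ROLE_BASE = "base"

LABEL_VESSEL = "vessel"
LABEL_SPECIOUS = "specious"
LABEL_UNLABELED = "unlabeled"


@dataclass
class Node:
    id: int
    x: float
    y: float
    role: str = ROLE_END

    @property
    def pos(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class Segment:
    """A skeleton segment between two nodes.

    ``polyline`` is an (N, 2) float array of (x, y) points ordered from
    ``node_a`` to ``node_b``; ``radii`` holds the vessel radius sampled at
    equidistant arc-length positions along the polyline.
    """

    id: int
    node_a: int
    node_b: int
    polyline: np.ndarray
    radii: np.ndarray = field(default_factory=lambda: np.empty(0))
    label: str = LABEL_UNLABELED

    @property
    def length(self) -> float:
        """Arc length of the polyline in pixels."""
        if len(self.polyline) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)))

    def other(self, node_id: int) -> int:
        return self.node_b if node_id == self.node_a else self.node_a

    def mean_x(self) -> float:
        return float(np.mean(self.polyline[:, 0]))

    def mean_y(self) -> float:
        return float(np.mean(self.polyline[:, 1]))


class SkeletonGraph:
    """Mutable node/segment graph with role bookkeeping."""

    def __init__(self):
        self.nodes: dict[int, Node] = {}
        self.segments: dict[int, Segment] = {}

    # -- construction -------------------------------------------------

    def add_node(self, x: float, y: float, role: str = ROLE_END, node_id: int | None = None) -> int:
        nid = node_id if node_id is not None else (max(self.nodes, default=0) + 1)
        if nid in self.nodes:
            raise ValueError(f"duplicate node id {nid}")
        self.nodes[nid] = Node(nid, float(x), float(y), role)
        return nid

    def add_segment(
        self,
        node_a: int,
        node_b: int,
        polyline: np.ndarray | None = None,
        radii: np.ndarray | None = None,
        segment_id: int | None = None,
        label: str = LABEL_UNLABELED,
    ) -> int:
        if node_a not in self.nodes or node_b not in self.nodes:
            raise KeyError("segment endpoints must be existing nodes")
        sid = segment_id if segment_id is not None else (max(self.segments, default=0) + 1)
        if sid in self.segments:
            raise ValueError(f"duplicate segment id {sid}")
        if polyline is None:
            a, b = self.nodes[node_a], self.nodes[node_b]
            polyline = np.array([[a.x, a.y], [b.x, b.y]], dtype=float)
        polyline = np.asarray(polyline, dtype=float)
        radii = np.empty(0) if radii is None else np.asarray(radii, dtype=float)
        self.segments[sid] = Segment(sid, node_a, node_b, polyline, radii, label)
        return sid

    # -- queries ------------------------------------------------------

    def degree(self, node_id: int) -> int:
        return sum(1 for s in self.segments.values() if node_id in (s.node_a, s.node_b))

    def incident_segments(self, node_id: int) -> list[Segment]:
        return [s for s in self.segments.values() if node_id in (s.node_a, s.node_b)]

    def neighbors(self, node_id: int) -> list[int]:
        return [s.other(node_id) for s in self.incident_segments(node_id)]

    def segment_between(self, a: int, b: int) -> Segment | None:
        for s in self.segments.values():
            if {s.node_a, s.node_b} == {a, b}:
                return s
        return None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def nodes_with_role(self, role: str) -> list[int]:
        return sorted(nid for nid, n in self.nodes.items() if n.role == role)

    # -- mutation -----------------------------------------------------

    def remove_segment(self, segment_id: int) -> None:
        del self.segments[segment_id]

    def remove_node(self, node_id: int) -> None:
        if self.incident_segments(node_id):
            raise ValueError("cannot remove a node with incident segments")
        del self.nodes[node_id]

    def relabel_roles(self, preserve_base: bool = True) -> None:
        """Reassign node roles from current degrees.

        Degree 1 -> end, 2 -> junction, >=3 -> branch.  Nodes already
        marked ``base`` keep that role when ``preserve_base``.
        """
        for node in self.nodes.values():
            if preserve_base and node.role == ROLE_BASE:
                continue
            d = self.degree(node.id)
            node.role = ROLE_END if d <= 1 else (ROLE_JUNCTION if d == 2 else ROLE_BRANCH)

    def drop_orphans(self) -> list[int]:
        """Remove degree-0 nodes; returns the removed ids."""
        orphans = [nid for nid in self.nodes if self.degree(nid) == 0]
        for nid in orphans:
            del self.nodes[nid]
        return orphans

    def merge(self, other: "SkeletonGraph") -> dict[int, int]:
        """Absorb another graph (disjoint geometry); returns the node-id
        remapping applied to ``other``'s nodes."""
        n_off = max(self.nodes, default=0)
        s_off = max(self.segments, default=0)
        remap = {}
        for nid, n in sorted(other.nodes.items()):
            remap[nid] = nid + n_off
            self.nodes[nid + n_off] = Node(nid + n_off, n.x, n.y, n.role)
        for sid, s in sorted(other.segments.items()):
            self.segments[sid + s_off] = Segment(
                sid + s_off, remap[s.node_a], remap[s.node_b],
                s.polyline.copy(), s.radii.copy(), s.label,
            )
        return remap

    def copy(self) -> "SkeletonGraph":
        g = SkeletonGraph()
        for nid, n in self.nodes.items():
            g.nodes[nid] = replace(n)
        for sid, s in self.segments.items():
            g.segments[sid] = Segment(sid, s.node_a, s.node_b, s.polyline.copy(), s.radii.copy(), s.label)
        return g

    # -- interop ------------------------------------------------------

    def to_networkx(self, weight: str = "length") -> nx.Graph:
        g = nx.Graph()
        for nid, n in self.nodes.items():
            g.add_node(nid, x=n.x, y=n.y, role=n.role)
        for sid, s in self.segments.items():
            g.add_edge(s.node_a, s.node_b, segment_id=sid, length=s.length, label=s.label)
        return g

    def connected_components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "coordinate_convention": "0-based, x=col, y=row, monolayer at max y",
            "nodes": [
                {"id": n.id, "x": n.x, "y": n.y, "role": n.role}
                for n in sorted(self.nodes.values(), key=lambda n: n.id)
            ],
            "segments": [
                {
                    "id": s.id,
                    "node_a": s.node_a,
                    "node_b": s.node_b,
                    "polyline": np.asarray(s.polyline).tolist(),
                    "radii": np.asarray(s.radii).tolist(),
                    "label": s.label,
                }
                for s in sorted(self.segments.values(), key=lambda s: s.id)
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SkeletonGraph":
        g = cls()
        for n in d["nodes"]:
            g.add_node(n["x"], n["y"], n.get("role", ROLE_END), node_id=n["id"])
        for s in d["segments"]:
            g.add_segment(
                s["node_a"],
                s["node_b"],
                polyline=np.asarray(s["polyline"], dtype=float),
                radii=np.asarray(s.get("radii", []), dtype=float),
                segment_id=s["id"],
                label=s.get("label", LABEL_UNLABELED),
            )
        return g

    @classmethod
    def from_json(cls, path) -> "SkeletonGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_graphml(self, path) -> None:
        g = self.to_networkx()
        # GraphML cannot store arrays; keep scalar attributes only
        nx.write_graphml(g, path)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SkeletonGraph(nodes={self.n_nodes}, segments={self.n_segments})"


def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline at ``n`` equidistant arc-length positions."""
    points = np.asarray(points, dtype=float)
    if len(points) == 1:
        return np.repeat(points, n, axis=0)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if t[-1] == 0:
        return np.repeat(points[:1], n, axis=0)
    ts = np.linspace(0.0, t[-1], n)
    x = np.interp(ts, t, points[:, 0])
    y = np.interp(ts, t, points[:, 1])
    return np.column_stack([x, y])
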