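"""Frame-to-frame association of sprouts and branches.

Sprouts (route groups sharing a base node) are matched between consecutive
frames by their average x-positions — distinct sprouts do not overlap, so
their skeletons differ clearly in x.  Within each matched sprout pair,
branch nodes are associated one-to-one by the Hungarian method on their
pairwise Euclidean distance matrix; when the later frame has more branch
nodes (new branches forming) the cost matrix is padded with a constant
``c0`` larger than every real distance, and columns assigned to padded
rows are declared new.  Matched branch nodes then induce a segment
correspondence (nearest mean x), and a per-branch history table records
each branch's route in every frame from its birth on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .branching import BranchRoute, Sprout
from .graph import ROLE_BASE, ROLE_BRANCH, SkeletonGraph

logger = logging.getLogger(__name__)


@dataclass
class CostMatrix:
    C: np.ndarray          # n1 x n2 Euclidean distances
    P: np.ndarray          # n2 x n2 padded square matrix
    c0: float              # padding constant, > all entries of C
    transposed: bool = False  # True when n2 < n1 forced column padding


@dataclass
class Assignment:
    Q: np.ndarray                       # n x n binary matrix, one 1 per row/col
    pairs: list[tuple[int, int]]        # (row, col) with a real (non-padded) cost
    new_columns: list[int]              # columns matched to padded rows
    cost: float


def build_cost_matrix(
    nodes_t: np.ndarray, nodes_t1: np.ndarray, image_diagonal: float | None = None
) -> CostMatrix:
    """Pairwise-distance cost matrix, padded square.

    ``c0`` is the largest real distance plus the image diagonal — strictly
    larger than every true cost while keeping the matrix well conditioned.
    A shrinking frame (n2 < n1) is outside the method's stated assumption;
    it is handled by transposed padding with a warning.
    """
    a = np.atleast_2d(np.asarray(nodes_t, dtype=float))
    b = np.atleast_2d(np.asarray(nodes_t1, dtype=float))
    n1 = 0 if a.size == 0 else len(a)
    n2 = 0 if b.size == 0 else len(b)
    C = cdist(a, b) if n1 and n2 else np.zeros((n1, n2))

    if image_diagonal is None:
        pts = np.vstack([p for p in (a, b) if p.size]) if (n1 or n2) else np.zeros((1, 2))
        span = pts.max(axis=0) - pts.min(axis=0)
        image_diagonal = float(np.hypot(*span)) + 1.0
    c0 = float(C.max() if C.size else 0.0) + image_diagonal

    transposed = False
    if n2 < n1:
        warnings.warn(
            "fewer branch nodes in the later frame (retraction); padding columns instead",
            stacklevel=2,
        )
        transposed = True
        n = n1
        P = np.full((n, n), c0)
        P[:, :n2] = C
    else:
        n = n2
        P = np.full((n, n), c0)
        if n1:
            P[:n1, :] = C
    return CostMatrix(C=C, P=P, c0=c0, transposed=transposed)


def solve_assignment(P: np.ndarray, c0: float | None = None) -> Assignment:
    """Minimum-cost one-to-one assignment on a square nonnegative matrix.

    Columns whose assigned cost equals the padding constant are reported as
    new.  The solution minimizes sum(p_ij q_ij) with exactly one 1 per row
    and column.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    n = P.shape[0]
    if n == 0:
        return Assignment(Q=np.zeros((0, 0)), pairs=[], new_columns=[], cost=0.0)
    rows, cols = linear_sum_assignment(P)
    Q = np.zeros((n, n), dtype=int)
    Q[rows, cols] = 1
    cost = float(P[rows, cols].sum())
    pairs, new_cols = [], []
    for r, c in zip(rows, cols):
        if c0 is not None and P[r, c] >= c0 - 1e-9:
            new_cols.append(int(c))
        else:
            pairs.append((int(r), int(c)))
    return Assignment(Q=Q, pairs=pairs, new_columns=sorted(new_cols), cost=cost)


def associate_sprouts(
    sprouts_t: list[Sprout], sprouts_t1: list[Sprout]
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Nearest-neighbour matching of sprouts by mean x-position.

    Returns (matched index pairs, new sprout indices at t+1, terminated
    sprout indices at t).  Ties in |dx| break toward the smaller x.
    """
    x_t = np.array([[s.mean_x, 0.0] for s in sprouts_t])
    x_t1 = np.array([[s.mean_x, 0.0] for s in sprouts_t1])
    cm = build_cost_matrix(x_t, x_t1)
    asg = solve_assignment(cm.P, cm.c0)
    if cm.transposed:
        matched = [(i, j) for i, j in asg.pairs]
        new = []
        terminated = [i for i in range(len(sprouts_t)) if i not in {p[0] for p in matched}]
        if terminated:
            warnings.warn(f"sprouts terminated at frame t: {terminated}", stacklevel=2)
    else:
        matched = asg.pairs
        new = asg.new_columns
        terminated = []
    return matched, new, terminated


@dataclass
class NodeAssociation:
    node_pairs: dict[int, int]          # old branch-node id -> new branch-node id
    new_nodes: list[int]                # new-frame branch node ids without a match
    segment_pairs: dict[int, int]       # old segment id -> new segment id
    new_segments: list[int]             # new-frame segment ids labeled new branches


def _sprout_branch_nodes(graph: SkeletonGraph, sprout: Sprout, routes: list[BranchRoute]) -> list[int]:
    ids = []
    for ri in sprout.route_indices:
        for nid in routes[ri].nodes:
            if graph.nodes[nid].role == ROLE_BRANCH and nid not in ids:
                ids.append(nid)
    return sorted(ids)


def _sprout_segments(graph: SkeletonGraph, sprout: Sprout, routes: list[BranchRoute]) -> set[int]:
    g = graph.to_networkx()
    sids = set()
    for ri in sprout.route_indices:
        nodes = routes[ri].nodes
        for u, v in zip(nodes, nodes[1:]):
            sids.add(g.edges[u, v]["segment_id"])
    return sids


def associate_branch_nodes(
    graph_t: SkeletonGraph,
    routes_t: list[BranchRoute],
    sprout_t: Sprout,
    graph_t1: SkeletonGraph,
    routes_t1: list[BranchRoute],
    sprout_t1: Sprout,
    image_diagonal: float | None = None,
) -> NodeAssociation:
    """Hungarian matching of branch nodes within one matched sprout pair,
    followed by mean-x matching of the segments incident to matched nodes.
    Segments incident only to unmatched (new) nodes are new branches."""
    old_ids = _sprout_branch_nodes(graph_t, sprout_t, routes_t)
    new_ids = _sprout_branch_nodes(graph_t1, sprout_t1, routes_t1)
    old_pos = np.array([[graph_t.nodes[i].x, graph_t.nodes[i].y] for i in old_ids]).reshape(-1, 2)
    new_pos = np.array([[graph_t1.nodes[i].x, graph_t1.nodes[i].y] for i in new_ids]).reshape(-1, 2)

    cm = build_cost_matrix(old_pos, new_pos, image_diagonal)
    asg = solve_assignment(cm.P, cm.c0)
    if cm.transposed:
        node_pairs = {old_ids[i]: new_ids[j] for i, j in asg.pairs}
        unmatched_new: list[int] = []
    else:
        node_pairs = {old_ids[i]: new_ids[j] for i, j in asg.pairs}
        unmatched_new = [new_ids[j] for j in asg.new_columns]

    segs_t = _sprout_segments(graph_t, sprout_t, routes_t)
    segs_t1 = _sprout_segments(graph_t1, sprout_t1, routes_t1)

    segment_pairs: dict[int, int] = {}
    used_new: set[int] = set()
    for old_n, new_n in sorted(node_pairs.items()):
        olds = [s for s in graph_t.incident_segments(old_n) if s.id in segs_t and s.id not in segment_pairs]
        news = [s for s in graph_t1.incident_segments(new_n) if s.id in segs_t1 and s.id not in used_new]
        # greedy nearest mean-x pairing; near-equal x resolved by mean y
        cand = sorted(
            ((abs(a.mean_x() - b.mean_x()), abs(a.mean_y() - b.mean_y()), a.id, b.id)
             for a in olds for b in news),
            key=lambda t: (round(t[0], 6), round(t[1], 6), t[2], t[3]),
        )
        for dx, dy, a_id, b_id in cand:
            if a_id in segment_pairs or b_id in used_new:
                continue
            segment_pairs[a_id] = b_id
            used_new.add(b_id)

    new_segments = sorted(
        sid for sid in segs_t1
        if sid not in used_new
        and any(n in unmatched_new for n in (graph_t1.segments[sid].node_a, graph_t1.segments[sid].node_b))
    )
    return NodeAssociation(
        node_pairs=node_pairs,
        new_nodes=unmatched_new,
        segment_pairs=segment_pairs,
        new_segments=new_segments,
    )


# ---------------------------------------------------------------------------
# branch history

@dataclass
class BranchRecord:
    branch_id: int
    birth_frame: int
    sprout_key: int                      # stable sprout identity
    routes: dict[int, list[int]] = field(default_factory=dict)   # frame -> node list
    tips: dict[int, tuple[float, float]] = field(default_factory=dict)
    lengths: dict[int, float] = field(default_factory=dict)
    widths: dict[int, float] = field(default_factory=dict)


class BranchHistory:
    """Per-branch route table over frames (one row per branch)."""

    def __init__(self):
        self.records: dict[int, BranchRecord] = {}
        self._next_id = 1

    def open_branch(self, frame: int, sprout_key: int, route: BranchRoute) -> int:
        bid = self._next_id
        self._next_id += 1
        rec = BranchRecord(branch_id=bid, birth_frame=frame, sprout_key=sprout_key)
        self.records[bid] = rec
        self._store(rec, frame, route)
        return bid

    def extend_branch(self, branch_id: int, frame: int, route: BranchRoute) -> None:
        if branch_id not in self.records:
            raise KeyError(f"unknown branch {branch_id}")
        self._store(self.records[branch_id], frame, route)

    @staticmethod
    def _store(rec: BranchRecord, frame: int, route: BranchRoute) -> None:
        rec.routes[frame] = list(route.nodes)
        rec.tips[frame] = (float(route.polyline[-1, 0]), float(route.polyline[-1, 1]))
        rec.lengths[frame] = route.length
        rec.widths[frame] = route.mean_width

    @property
    def n_frames(self) -> int:
        return 1 + max((f for r in self.records.values() for f in r.routes), default=-1)

    def route_of(self, branch_id: int, frame: int) -> list[int] | None:
        return self.records[branch_id].routes.get(frame)

    def table(self) -> pd.DataFrame:
        """History in the frames-by-branch layout: one row per branch, the
        route it follows at each frame (empty before its birth)."""
        frames = range(self.n_frames)
        rows = {}
        for bid, rec in sorted(self.records.items()):
            rows[bid] = {
                f"frame_{f}": (" ".join(map(str, rec.routes[f])) if f in rec.routes else "")
                for f in frames
            }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "branch"
        return df

    def long_table(self) -> pd.DataFrame:
        rows = []
        for bid, rec in sorted(self.records.items()):
            for f in sorted(rec.routes):
                rows.append({
                    "frame": f,
                    "branch_id": bid,
                    "sprout_id": rec.sprout_key,
                    "route": " ".join(map(str, rec.routes[f])),
                    "length_px": round(rec.lengths[f], 2),
                    "width_px": round(rec.widths[f], 2),
                    "is_new": f == rec.birth_frame,
                })
        return pd.DataFrame(rows)


@dataclass
class TrackedFrame:
    """One analyzed frame: graph after base determination, routes, sprouts."""

    graph: SkeletonGraph
    routes: list[BranchRoute]
    sprouts: list[Sprout]


def _resample(points: np.ndarray, n: int, upto: float | None = None) -> np.ndarray:
    """Resample a polyline at ``n`` equidistant points, optionally only up
    to arc length ``upto``."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    stop = t[-1] if upto is None else min(upto, t[-1])
    ts = np.linspace(0.0, stop, n)
    return np.column_stack([np.interp(ts, t, pts[:, 0]), np.interp(ts, t, pts[:, 1])])


def _point_at_arc(points: np.ndarray, s: float) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    s = min(max(s, 0.0), t[-1])
    return np.array([np.interp(s, t, pts[:, 0]), np.interp(s, t, pts[:, 1])])


ROUTE_MATCH_GATE = 20.0      # px: worse scores do not continue a branch
_LOOKAHEAD = 15.0            # px past the old tip used to separate sibling arms


def _route_continuation_score(old: BranchRoute, new: BranchRoute) -> float:
    """How well ``new`` continues ``old``: mean distance between the old
    polyline and the new one truncated to the old arc length, plus the
    mismatch of the first ``_LOOKAHEAD`` px of further growth against the
    old terminal direction (which separates the two arms of a fresh fork,
    both of which contain the old route as a geometric prefix)."""
    a = _resample(old.polyline, 20)
    b = _resample(new.polyline, 20, upto=old.length)
    trunk = float(np.mean(np.linalg.norm(a - b, axis=1)))
    tip = np.asarray(old.polyline[-1], dtype=float)
    # local growth direction over the last stretch of the old route
    start = _point_at_arc(old.polyline, max(old.length - _LOOKAHEAD, 0.0))
    d = tip - start
    nd = np.linalg.norm(d)
    if nd > 0 and new.length > old.length + 1.0:
        # mean deviation of the new growth from a straight continuation,
        # sampled over the whole extension
        ss = np.linspace(old.length, new.length, 6)[1:]
        devs = [
            float(np.linalg.norm(tip + d / nd * (s - old.length) - _point_at_arc(new.polyline, s)))
            for s in ss
        ]
        ahead = float(np.mean(devs))
    else:
        ahead = 0.0
    return trunk + 0.5 * ahead


def _match_routes(
    frame_t: TrackedFrame,
    frame_t1: TrackedFrame,
    sp_t: Sprout,
    sp_t1: Sprout,
    assoc: NodeAssociation,
    base_map: dict[int, int],
) -> tuple[dict[int, int], list[int]]:
    """Map old route indices to continuing new route indices.

    Because a branch only elongates between frames, its old route is a
    geometric prefix of its new route; continuation is decided by an
    optimal one-to-one assignment on the prefix-agreement score, gated so
    that a poor fit opens a new branch instead.  (The node/segment-level
    correspondence computed by :func:`associate_branch_nodes` remains the
    per-node statement of the same matching; the geometric roll-up is
    robust to frame-to-frame topology flicker of the skeleton.)
    """
    olds = sorted(sp_t.route_indices)
    news = sorted(sp_t1.route_indices)
    if not olds or not news:
        return {}, news
    S = np.empty((len(olds), len(news)))
    for i, oi in enumerate(olds):
        for j, ni in enumerate(news):
            S[i, j] = _route_continuation_score(frame_t.routes[oi], frame_t1.routes[ni])
    big = ROUTE_MATCH_GATE * 1000.0
    P = np.where(S <= ROUTE_MATCH_GATE, S, big)
    rows, cols = linear_sum_assignment(P)
    continuations = {
        olds[i]: news[j] for i, j in zip(rows, cols) if P[i, j] < big
    }
    taken = set(continuations.values())
    return continuations, [ni for ni in news if ni not in taken]


def track_sequence(frames: list[TrackedFrame], image_diagonal: float | None = None) -> BranchHistory:
    """Associate branches across a whole analyzed sequence.

    Frame 0 opens one branch per route; each subsequent frame is matched
    to its predecessor (sprouts by mean x, branch nodes by the Hungarian
    method, routes by node-correspondence extension) and the history is
    updated: existing branches extend, unmatched new routes open branches
    born at that frame.
    """
    history = BranchHistory()
    if not frames:
        return history

    # branch id carried by each route index of the current frame
    route_owner: dict[int, int] = {}
    sprout_keys: dict[int, int] = {}
    next_sprout_key = 1
    for si, sp in enumerate(frames[0].sprouts):
        sprout_keys[si] = next_sprout_key
        next_sprout_key += 1
        for ri in sp.route_indices:
            route_owner[ri] = history.open_branch(0, sprout_keys[si], frames[0].routes[ri])

    for f in range(1, len(frames)):
        prev, curr = frames[f - 1], frames[f]
        matched, new_sprouts, terminated = associate_sprouts(prev.sprouts, curr.sprouts)
        if terminated:
            logger.warning("frame %d: %d sprout(s) disappeared", f, len(terminated))
        new_owner: dict[int, int] = {}
        new_keys: dict[int, int] = {}

        for si, sj in matched:
            sp_t, sp_t1 = prev.sprouts[si], curr.sprouts[sj]
            new_keys[sj] = sprout_keys.get(si, 0)
            assoc = associate_branch_nodes(
                prev.graph, prev.routes, sp_t, curr.graph, curr.routes, sp_t1, image_diagonal
            )
            base_map = {sp_t.base_node: sp_t1.base_node}
            cont, new_r = _match_routes(prev, curr, sp_t, sp_t1, assoc, base_map)
            for oi, ni in cont.items():
                bid = route_owner.get(oi)
                if bid is None:
                    continue
                history.extend_branch(bid, f, curr.routes[ni])
                new_owner[ni] = bid
            for ni in new_r:
                new_owner[ni] = history.open_branch(f, new_keys[sj], curr.routes[ni])

        for sj in new_sprouts:
            new_keys[sj] = next_sprout_key
            next_sprout_key += 1
            for ri in curr.sprouts[sj].route_indices:
                new_owner[ri] = history.open_branch(f, new_keys[sj], curr.routes[ri])

        route_owner = new_owner
        sprout_keys = new_keys

    return history


# ---------------------------------------------------------------------------
# evaluation against phantom truth

def trajectory_metrics(
    history: BranchHistory,
    truth_tips: dict[int, dict[int, tuple[float, float]]],
    tolerance: float = 15.0,
) -> dict:
    """Precision/recall of branch trajectories against ground truth.

    A detected branch identifies a true one when their birth frames agree
    within one frame and the tip positions lie within ``tolerance`` px in
    every frame both cover; the pairing is one-to-one (greedy by mean tip
    distance).
    """
    det = {
        bid: (rec.birth_frame, rec.tips) for bid, rec in history.records.items()
    }
    candidates = []
    for d_id, (d_birth, d_tips) in det.items():
        for t_id, t_tips in truth_tips.items():
            t_birth = min(t_tips)
            common = sorted(set(d_tips) & set(t_tips))
            if not common or abs(d_birth - t_birth) > 1:
                continue
            dists = [
                float(np.hypot(d_tips[f][0] - t_tips[f][0], d_tips[f][1] - t_tips[f][1]))
                for f in common
            ]
            if max(dists) <= tolerance:
                candidates.append((float(np.mean(dists)), d_id, t_id))
    candidates.sort()
    used_d, used_t = set(), set()
    matched = 0
    for _, d_id, t_id in candidates:
        if d_id in used_d or t_id in used_t:
            continue
        used_d.add(d_id)
        used_t.add(t_id)
        matched += 1
    n_det = len(det)
    n_true = len(truth_tips)
    return {
        "matched": matched,
        "n_detected": n_det,
        "n_true": n_true,
        "precision": matched / n_det if n_det else 1.0,
        "recall": matched / n_true if n_true else 1.0,
    }
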