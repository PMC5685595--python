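"""Synthetic sprouting-region phantoms with exact ground truth.

No public image data accompanies the tracking problem this package solves,
so every stage is validated against phantoms: binary vessel masks (tubes
swept along known centerlines, anchored in a monolayer band), grayscale
phase-contrast-like renderings with trapezoidal registration posts, and
time-lapse sequences with scripted elongation, branching events and camera
jitter.  The generator returns the exact centerline graph, node roles,
branch routes, persistent branch identities, cell positions and phenotype
labels for every frame, which downstream modules are measured against.

Canonical orientation: the monolayer lies along the bottom image edge and
sprouts grow toward decreasing row index; ``x`` is the column axis.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from skimage import draw as skdraw
from skimage.transform import SimilarityTransform, warp

from .graph import ROLE_BASE, ROLE_BRANCH, ROLE_END, SkeletonGraph, polyline_length

# minimum clearance between distinct sprouts, in tube diameters of base x
MIN_SPROUT_SEPARATION_DIAMETERS = 3.0


@dataclass
class BranchSpec:
    """One tube of a sprout: centerline control points (proximal to
    distal), a radius profile (constant, or (r_base, r_tip) linear taper)
    and children attached at arc-length fractions of this branch."""

    points: list[tuple[float, float]]
    radius: float | tuple[float, float] = 5.0
    children: list[tuple[float, "BranchSpec"]] = field(default_factory=list)

    def radius_at(self, frac: float) -> float:
        if isinstance(self.radius, (tuple, list)):
            r0, r1 = self.radius
            return float(r0 + (r1 - r0) * frac)
        return float(self.radius)

    def max_radius(self) -> float:
        r = max(self.radius) if isinstance(self.radius, (tuple, list)) else self.radius
        return max([r] + [c.max_radius() for _, c in self.children])


@dataclass
class PhantomSpec:
    """A static sprouting-region phantom.

    ``sprouts`` are trees of :class:`BranchSpec`; each root's first control
    point must sit on the monolayer's top edge.  ``boundary_noise_amplitude``
    modulates the tube radius along arc length with smooth noise, emulating
    the ragged boundaries of segmented phase-contrast vessels.
    """

    image_size: tuple[int, int] = (300, 400)        # (H, W)
    monolayer_height: int = 40
    sprouts: list[BranchSpec] = field(default_factory=list)
    boundary_noise_amplitude: float = 0.0
    interface_coeffs: tuple[float, float, float] | None = None  # y = a x^2 + b x + c
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if not 0 < self.monolayer_height < h:
            raise ValueError("monolayer_height must lie inside the image")
        for s in self.sprouts:
            _validate_branch(s, h, w)
        bases = [s.points[0][0] for s in self.sprouts]
        if len(bases) > 1:
            min_sep = MIN_SPROUT_SEPARATION_DIAMETERS * 2 * max(s.max_radius() for s in self.sprouts)
            bx = sorted(bases)
            if min(b2 - b1 for b1, b2 in zip(bx, bx[1:])) < min_sep:
                raise ValueError(
                    f"distinct sprouts must be >= {min_sep:.0f} px apart in base x "
                    "(three tube diameters); they must not overlap"
                )

    def interface_y(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.interface_coeffs is None:
            return np.full_like(np.asarray(x, dtype=float), self.image_size[0] - self.monolayer_height)
        a, b, c = self.interface_coeffs
        return a * np.asarray(x, dtype=float) ** 2 + b * np.asarray(x, dtype=float) + c

    def crop_to_gel(self, mask: np.ndarray) -> np.ndarray:
        """Zero out everything at or below the cell-gel interface — what the
        preprocessing gel-region masking does to a segmented image."""
        h, w = self.image_size
        yy, xx = np.mgrid[0:h, 0:w]
        out = np.asarray(mask).copy()
        out[yy >= self.interface_y(xx)] = False
        return out


def _validate_branch(b: BranchSpec, h: int, w: int) -> None:
    if len(b.points) < 2:
        raise ValueError("branch needs >= 2 control points")
    for x, y in b.points:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"control point ({x}, {y}) outside image")
    radii = b.radius if isinstance(b.radius, (tuple, list)) else (b.radius,)
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    for frac, child in b.children:
        if not 0 < frac <= 1:
            raise ValueError("child attach fraction must be in (0, 1]")
        _validate_branch(child, h, w)


@dataclass
class FrameTruth:
    """Exact per-frame ground truth in canonical (unjittered) coordinates."""

    graph: SkeletonGraph
    routes: list[list[int]]            # node-id sequences, base ... end
    route_branch_ids: list[int]        # persistent branch identity per route
    cells: pd.DataFrame                # cell_id, x, y, phenotype, branch_id, shared
    transform: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 1.0)  # dx, dy, dtheta_deg, scale
    mask_canonical: np.ndarray | None = None   # pre-jitter binary mask


@dataclass
class GroundTruth:
    frames: list[FrameTruth]

    @property
    def frame(self) -> FrameTruth:
        """Single-frame convenience accessor."""
        return self.frames[0]

    def to_dict(self) -> dict:
        return {
            "frames": [
                {
                    "graph": f.graph.to_dict(),
                    "routes": f.routes,
                    "route_branch_ids": f.route_branch_ids,
                    "transform": list(f.transform),
                }
                for f in self.frames
            ]
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def cells_table(self) -> pd.DataFrame:
        out = []
        for i, f in enumerate(self.frames):
            d = f.cells.copy()
            d.insert(0, "frame", i)
            out.append(d)
        return pd.concat(out, ignore_index=True)

    def cells_to_csv(self, path) -> None:
        self.cells_table().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry helpers

def _densify(points: np.ndarray, step: float = 0.5) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(np.ceil(t[-1] / step)) + 1)
    ts = np.linspace(0, t[-1], n)
    return np.column_stack([np.interp(ts, t, points[:, 0]), np.interp(ts, t, points[:, 1])])


def _point_at(path: np.ndarray, s: float) -> np.ndarray:
    """Point at arc length ``s`` along a polyline."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    s = float(np.clip(s, 0, t[-1]))
    return np.array([np.interp(s, t, path[:, 0]), np.interp(s, t, path[:, 1])])


def _draw_tube(canvas: np.ndarray, path: np.ndarray, radii: np.ndarray) -> None:
    h, w = canvas.shape
    for (x, y), r in zip(path, radii):
        rr, cc = skdraw.disk((y, x), max(r, 0.6), shape=(h, w))
        canvas[rr, cc] = True


def _smooth_noise(n: int, amplitude: float, rng: np.random.Generator, corr: float = 8.0) -> np.ndarray:
    """Smooth bounded noise in [-amplitude, +amplitude] (px).

    The amplitude is a peak, not a standard deviation: segmentation
    raggedness perturbs a vessel boundary by a bounded amount, it does not
    pinch the tube off.
    """
    if amplitude <= 0 or n < 2:
        return np.zeros(n)
    raw = gaussian_filter1d(rng.standard_normal(n), corr / 0.5, mode="wrap")
    sd = raw.std()
    if sd == 0:
        return np.zeros(n)
    return amplitude * np.clip(raw / (2.0 * sd), -1.0, 1.0)


# ---------------------------------------------------------------------------
# static phantom

def _build_truth_graph(spec: PhantomSpec) -> tuple[SkeletonGraph, list[list[int]], list[np.ndarray]]:
    """Exact centerline graph, routes and per-route polylines for a spec."""
    g = SkeletonGraph()
    routes: list[list[int]] = []
    route_polys: list[np.ndarray] = []

    def add_branch(branch: BranchSpec, start_node: int, prefix_nodes: list[int], prefix_poly: np.ndarray | None):
        path = _densify(np.asarray(branch.points, dtype=float))
        seg_len = np.linalg.norm(np.diff(path, axis=0), axis=1)
        total = float(seg_len.sum())
        cuts = sorted((frac * total, child) for frac, child in branch.children)
        s_prev = 0.0
        prev_node = start_node
        nodes_here = list(prefix_nodes)
        for s_cut, child in cuts:
            p = _point_at(path, s_cut)
            nid = g.add_node(p[0], p[1], ROLE_BRANCH)
            g.add_segment(prev_node, nid, polyline=_clip_path(path, s_prev, s_cut))
            nodes_here.append(nid)
            sub_prefix_poly = _concat(prefix_poly, _clip_path(path, 0.0, s_cut))
            add_branch(child, nid, list(nodes_here), sub_prefix_poly)
            prev_node, s_prev = nid, s_cut
        tip = path[-1]
        tid = g.add_node(tip[0], tip[1], ROLE_END)
        g.add_segment(prev_node, tid, polyline=_clip_path(path, s_prev, total))
        routes.append(nodes_here + [tid])
        route_polys.append(_concat(prefix_poly, path))

    for sprout in spec.sprouts:
        x0, y0 = sprout.points[0]
        base = g.add_node(x0, y0, ROLE_BASE)
        add_branch(sprout, base, [base], None)
    return g, routes, route_polys


def _clip_path(path: np.ndarray, s0: float, s1: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    keep = (t > s0) & (t < s1)
    pts = [_point_at(path, s0)] + [p for p, k in zip(path, keep) if k] + [_point_at(path, s1)]
    return np.asarray(pts)


def _concat(a: np.ndarray | None, b: np.ndarray) -> np.ndarray:
    return b if a is None else np.vstack([a, b])


def _render_branch_masks(spec: PhantomSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """One mask per sprout (for overlap checking), tubes with noisy radii."""
    h, w = spec.image_size
    masks = []

    def paint(branch: BranchSpec, canvas: np.ndarray):
        path = _densify(np.asarray(branch.points, dtype=float))
        fracs = np.linspace(0, 1, len(path))
        radii = np.array([branch.radius_at(f) for f in fracs])
        radii = np.maximum(radii + _smooth_noise(len(path), spec.boundary_noise_amplitude, rng), 1.0)
        _draw_tube(canvas, path, radii)
        for _, child in branch.children:
            paint(child, canvas)

    for sprout in spec.sprouts:
        canvas = np.zeros((h, w), dtype=bool)
        paint(sprout, canvas)
        masks.append(canvas)
    return masks


def _monolayer_mask(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    return yy >= spec.interface_y(xx)


def _default_cells(routes: list[list[int]], polys: list[np.ndarray], spacing: float = 18.0,
                   tip_offset: float = 3.0) -> pd.DataFrame:
    """Cells along each route: one tip cell near the distal end, stalk cells
    behind it; trunk cells shared by several routes are flagged."""
    rows = []
    cid = 0
    seen: list[tuple[float, float]] = []
    for branch_id, poly in enumerate(polys, start=1):
        total = polyline_length(poly)
        positions = list(np.arange(spacing / 2, max(total - tip_offset, spacing / 2) - 1e-9, spacing))
        positions.append(max(total - tip_offset, 0.0))
        for k, s in enumerate(positions):
            p = _point_at(poly, s)
            dup = next((c for c in seen if math.hypot(c[0] - p[0], c[1] - p[1]) < 1.0), None)
            if dup is not None:
                # same physical trunk cell reached via another route
                for r in rows:
                    if math.hypot(r["x"] - p[0], r["y"] - p[1]) < 1.0:
                        r["shared"] = True
                continue
            cid += 1
            rows.append({
                "cell_id": cid,
                "x": float(p[0]),
                "y": float(p[1]),
                "phenotype": "tip" if k == len(positions) - 1 else "stalk",
                "branch_id": branch_id,
                "shared": False,
            })
            seen.append((p[0], p[1]))
    return pd.DataFrame(rows, columns=["cell_id", "x", "y", "phenotype", "branch_id", "shared"])


def generate_vessel_mask(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Binary vessel mask (tubes plus monolayer band) with exact truth.

    Raises ``ValueError`` if distinct sprouts overlap or sit closer than
    three tube diameters in base x — configurations the method assumes do
    not occur.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sprout_masks = _render_branch_masks(spec, rng)
    for i in range(len(sprout_masks)):
        for j in range(i + 1, len(sprout_masks)):
            if (sprout_masks[i] & sprout_masks[j]).any():
                raise ValueError(f"sprouts {i} and {j} overlap; rejected")
    mask = _monolayer_mask(spec)
    for m in sprout_masks:
        mask |= m
    graph, routes, polys = _build_truth_graph(spec)
    cells = _default_cells(routes, polys)
    truth = GroundTruth(frames=[FrameTruth(graph=graph, routes=routes,
                                           route_branch_ids=list(range(1, len(routes) + 1)),
                                           cells=cells)])
    return mask, truth


# ---------------------------------------------------------------------------
# time-lapse phantom

@dataclass
class TimelapseSpec:
    """Scripted growth of a sprouting region over daily frames.

    Initial sprouts come from the companion :class:`PhantomSpec`: each
    sprout's control polyline is its growth track, revealed at
    ``elongation_per_frame`` px per frame and extended procedurally (with
    seeded curvature noise) if the track runs out.  ``branching_events``
    fork a scripted parent branch at its current tip; ``new_sprout_events``
    start additional sprouts from the monolayer.  ``registration_jitter``
    holds one (dx, dy, dtheta_deg, scale) camera misalignment per frame.
    """

    n_frames: int = 6
    elongation_per_frame: float = 30.0
    branching_events: list[tuple[int, int, float]] = field(default_factory=list)  # (frame, parent branch id, angle_deg)
    new_sprout_events: list[tuple[int, float]] = field(default_factory=list)      # (frame, base x)
    registration_jitter: list[tuple[float, float, float, float]] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for f, *_ in self.branching_events:
            if f >= self.n_frames:
                raise ValueError(f"branching event at frame {f} >= n_frames")
        for f, _ in self.new_sprout_events:
            if f >= self.n_frames:
                raise ValueError(f"new sprout event at frame {f} >= n_frames")
        if self.registration_jitter is not None and len(self.registration_jitter) != self.n_frames:
            raise ValueError("registration_jitter must give one transform per frame")


@dataclass
class _DynBranch:
    id: int
    parent: int | None          # parent branch id
    birth: int                  # first frame present
    path: np.ndarray            # growth track so far, canonical coords
    radius: float
    fork_arc: float             # arc position on OWN path where it starts (0)
    fork_node_key: tuple | None # identity of the fork with parent


def _extend_path(path: np.ndarray, target_len: float, rng: np.random.Generator,
                 bounds: tuple[int, int], step: float = 5.0, wiggle: float = 0.06) -> np.ndarray:
    h, w = bounds
    cur = polyline_length(path)
    if cur >= target_len:
        return path
    pts = list(map(tuple, path))
    d = np.asarray(pts[-1]) - np.asarray(pts[-2])
    heading = math.atan2(d[1], d[0])
    while cur < target_len:
        heading += rng.normal(0, wiggle)
        x, y = pts[-1]
        # steer back toward the interior near borders
        if x < 25 and math.cos(heading) < 0:
            heading = math.pi - heading
        if x > w - 25 and math.cos(heading) > 0:
            heading = math.pi - heading
        if y < 25 and math.sin(heading) < 0:
            heading = -heading
        nxt = (x + step * math.cos(heading), y + step * math.sin(heading))
        nxt = (float(np.clip(nxt[0], 2, w - 3)), float(np.clip(nxt[1], 2, h - 3)))
        pts.append(nxt)
        cur += math.hypot(nxt[0] - x, nxt[1] - y)
    return np.asarray(pts)


def jitter_transform(dx: float, dy: float, dtheta_deg: float, scale: float,
                     image_size: tuple[int, int]) -> SimilarityTransform:
    """Similarity transform rotating/scaling about the image center then
    translating; maps canonical coordinates to jittered-frame coordinates."""
    h, w = image_size
    cy, cx = h / 2, w / 2
    return (
        SimilarityTransform(translation=(-cx, -cy))
        + SimilarityTransform(rotation=np.deg2rad(dtheta_deg), scale=scale)
        + SimilarityTransform(translation=(cx + dx, cy + dy))
    )


def generate_timelapse(pspec: PhantomSpec, tspec: TimelapseSpec) -> tuple[list[np.ndarray], GroundTruth]:
    """Masks and exact truth for a scripted time-lapse sequence.

    Elongation is monotone; branches appear exactly at scripted events and
    keep a persistent identity; per-frame similarity jitter (if any) is
    applied to the returned masks and recorded in the truth.
    """
    pspec.validate()
    tspec.validate()
    rng = np.random.default_rng(tspec.seed)
    h, w = pspec.image_size
    y_base = float(np.min(pspec.interface_y(np.arange(w)))) if pspec.interface_coeffs else h - pspec.monolayer_height

    branches: list[_DynBranch] = []
    for s in pspec.sprouts:
        branches.append(_DynBranch(id=len(branches) + 1, parent=None, birth=0,
                                   path=_densify(np.asarray(s.points, dtype=float), 2.0),
                                   radius=s.radius_at(0.0), fork_arc=0.0, fork_node_key=None))
    track_full = {b.id: b.path.copy() for b in branches}

    events_b = {}
    for f, pid, ang in tspec.branching_events:
        events_b.setdefault(f, []).append((pid, ang))
    events_s = {}
    for f, bx in tspec.new_sprout_events:
        events_s.setdefault(f, []).append(bx)

    frames: list[FrameTruth] = []
    masks: list[np.ndarray] = []
    visible: dict[int, np.ndarray] = {}

    for f in range(tspec.n_frames):
        # grow every existing branch by one frame of elongation
        for b in branches:
            age = f - b.birth + 1
            target = tspec.elongation_per_frame * age
            full = _extend_path(track_full[b.id], target, rng, (h, w))
            track_full[b.id] = full
            # visible prefix
            seg = np.linalg.norm(np.diff(full, axis=0), axis=1)
            t = np.concatenate([[0.0], np.cumsum(seg)])
            keep = t <= target
            vis = full[keep]
            if polyline_length(vis) < target and len(vis) < len(full):
                vis = np.vstack([vis, _point_at(full, target)])
            visible[b.id] = vis

        # scripted new sprouts
        for bx in events_s.get(f, []):
            nb = _DynBranch(id=len(branches) + 1, parent=None, birth=f,
                            path=np.array([[bx, y_base], [bx + rng.normal(0, 2), y_base - tspec.elongation_per_frame]]),
                            radius=pspec.sprouts[0].radius_at(0.0) if pspec.sprouts else 5.0,
                            fork_arc=0.0, fork_node_key=None)
            branches.append(nb)
            track_full[nb.id] = nb.path.copy()
            visible[nb.id] = nb.path.copy()

        # scripted branching events: fork where the parent's tip sat last
        # frame, so both arms carry one frame of growth past the fork
        for pid, ang in events_b.get(f, []):
            parent = next((b for b in branches if b.id == pid), None)
            if parent is None:
                raise ValueError(f"branching event references unknown branch {pid}")
            if parent.birth >= f:
                raise ValueError(f"branching event at frame {f} precedes branch {pid} growth")
            fork_arc = tspec.elongation_per_frame * (f - parent.birth)
            tip = _point_at(track_full[pid], fork_arc)
            ahead = _point_at(track_full[pid], fork_arc + 3.0)
            behind = _point_at(track_full[pid], max(fork_arc - 3.0, 0.0))
            d = ahead - behind
            heading = math.atan2(d[1], d[0]) + math.radians(ang)
            child_path = np.array([
                tip,
                [tip[0] + tspec.elongation_per_frame * math.cos(heading),
                 tip[1] + tspec.elongation_per_frame * math.sin(heading)],
            ])
            child_path[:, 0] = np.clip(child_path[:, 0], 2, w - 3)
            child_path[:, 1] = np.clip(child_path[:, 1], 2, h - 3)
            nb = _DynBranch(id=len(branches) + 1, parent=pid, birth=f,
                            path=child_path, radius=parent.radius * 0.9,
                            fork_arc=fork_arc,
                            fork_node_key=(pid, round(tip[0], 1), round(tip[1], 1)))
            branches.append(nb)
            track_full[nb.id] = nb.path.copy()
            visible[nb.id] = nb.path.copy()

        ft = _timelapse_frame_truth(pspec, tspec, branches, visible, f)
        ft.mask_canonical = _timelapse_frame_mask(pspec, branches, visible, f, rng)
        frames.append(ft)
        masks.append(ft.mask_canonical)

    # apply jitter to the returned masks and record it
    if tspec.registration_jitter is not None:
        for i, (dx, dy, dth, sc) in enumerate(tspec.registration_jitter):
            tf = jitter_transform(dx, dy, dth, sc, pspec.image_size)
            masks[i] = warp(masks[i].astype(float), tf.inverse, order=0, preserve_range=True) > 0.5
            frames[i].transform = (dx, dy, dth, sc)

    return masks, GroundTruth(frames=frames)


def render_timelapse(
    gt: GroundTruth,
    post_positions: list[float] | None = None,
    seed: int = 0,
    *,
    background: float = 100.0,
    separation: float = 60.0,
    noise_sigma: float = 10.0,
) -> list[np.ndarray]:
    """Grayscale renderings of a generated time-lapse.

    Vessels and posts are drawn in canonical device coordinates, the
    frame's recorded camera jitter warps the whole scene (posts included,
    as a misaligned camera would see them), and sensor noise is added
    last.
    """
    imgs = []
    for f, ft in enumerate(gt.frames):
        if ft.mask_canonical is None:
            raise ValueError("ground truth lacks canonical masks")
        clean = render_microscopy(
            ft.mask_canonical, post_positions, seed=seed + f,
            background=background, separation=separation, noise_sigma=0.0,
        )
        dx, dy, dth, sc = ft.transform
        if (dx, dy, dth, sc) != (0.0, 0.0, 0.0, 1.0):
            tf = jitter_transform(dx, dy, dth, sc, ft.mask_canonical.shape)
            clean = warp(clean, tf.inverse, order=1, preserve_range=True, cval=background)
        rng = np.random.default_rng(seed + 7919 * (f + 1))
        imgs.append(np.clip(clean + rng.normal(0, noise_sigma, clean.shape), 0, 255))
    return imgs


def _timelapse_frame_mask(pspec, branches, visible, f, rng) -> np.ndarray:
    h, w = pspec.image_size
    mask = _monolayer_mask(pspec)
    for b in branches:
        if b.birth > f:
            continue
        path = _densify(visible[b.id], 0.5)
        radii = np.maximum(
            b.radius + _smooth_noise(len(path), pspec.boundary_noise_amplitude, rng), 1.0
        )
        _draw_tube(mask, path, radii)
    return mask


def _timelapse_frame_truth(pspec, tspec, branches, visible, f) -> FrameTruth:
    """Truth graph for one frame, built from the dynamic branch forest."""
    g = SkeletonGraph()
    routes: list[list[int]] = []
    branch_ids: list[int] = []
    polys: list[np.ndarray] = []

    present = [b for b in branches if b.birth <= f]
    kids: dict[int, list] = {}
    for b in present:
        if b.parent is not None:
            kids.setdefault(b.parent, []).append(b)
    roots = [b for b in present if b.parent is None]

    def emit(branch, start_node, prefix_nodes, prefix_poly):
        path = visible[branch.id]
        total = polyline_length(path)
        cuts = sorted(
            ((c.fork_arc, c) for c in kids.get(branch.id, [])), key=lambda t: t[0]
        )
        prev_node, s_prev = start_node, 0.0
        nodes_here = list(prefix_nodes)
        for s_cut, child in cuts:
            s_cut = min(s_cut, total)
            p = _point_at(path, s_cut)
            nid = g.add_node(p[0], p[1], ROLE_BRANCH)
            g.add_segment(prev_node, nid, polyline=_clip_path(path, s_prev, s_cut))
            nodes_here.append(nid)
            emit(child, nid, list(nodes_here), _concat(prefix_poly, _clip_path(path, 0, s_cut)))
            prev_node, s_prev = nid, s_cut
        tid = g.add_node(path[-1][0], path[-1][1], ROLE_END)
        g.add_segment(prev_node, tid, polyline=_clip_path(path, s_prev, total))
        routes.append(nodes_here + [tid])
        branch_ids.append(branch.id)
        polys.append(_concat(prefix_poly, path))

    for root in roots:
        x0, y0 = visible[root.id][0]
        base = g.add_node(x0, y0, ROLE_BASE)
        emit(root, base, [base], None)

    cells = _default_cells(routes, polys)
    return FrameTruth(graph=g, routes=routes, route_branch_ids=branch_ids, cells=cells)


# ---------------------------------------------------------------------------
# rendering and tiling

def default_post_positions(image_size: tuple[int, int], n: int = 3) -> list[float]:
    """Evenly spaced post y-positions clear of the monolayer band."""
    h, _ = image_size
    return list(np.linspace(0.18 * h, 0.72 * h, n))


def render_microscopy(
    mask: np.ndarray,
    post_positions: list[float] | None = None,
    seed: int = 0,
    *,
    background: float = 100.0,
    separation: float = 60.0,
    noise_sigma: float = 10.0,
    post_intensity: float = 35.0,
    post_width: int = 16,
    post_halfheight: int = 12,
) -> np.ndarray:
    """Grayscale rendering of a binary phantom.

    Vessel foreground and background are drawn from two Gaussian intensity
    distributions separated by ``separation`` gray levels (a strongly
    bimodal histogram, so Otsu thresholding is well posed), with trapezoidal
    post silhouettes at the stated y positions on the left and right gel
    boundaries.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    rng = np.random.default_rng(seed)
    img = np.full((h, w), background, dtype=float)
    img[mask] += separation
    if post_positions:
        margin = 14  # keep posts fully inside so jitter never clips them
        for y in post_positions:
            for x0, direction in ((margin, 1), (w - 1 - margin, -1)):
                ys = [y - post_halfheight, y + post_halfheight,
                      y + 0.55 * post_halfheight, y - 0.55 * post_halfheight]
                xs = [x0, x0, x0 + direction * post_width, x0 + direction * post_width]
                rr, cc = skdraw.polygon(ys, xs, shape=(h, w))
                img[rr, cc] = post_intensity
    img += rng.normal(0, noise_sigma, size=(h, w))
    return np.clip(img, 0, 255)


@dataclass
class TileSet:
    tiles: list[np.ndarray]
    offsets: list[int]          # x offset of each tile in the source image

    def __iter__(self):
        return iter(self.tiles)

    def __len__(self):
        return len(self.tiles)


def split_tiles(image: np.ndarray, overlap_fraction: float, n_tiles: int | None = None) -> TileSet:
    """Split an image into horizontally overlapping tiles.

    Adjacent tiles share ``overlap_fraction`` of their width; offsets are
    recorded so stitching can be validated round-trip.  An image too small
    for two tiles is returned as a single tile.
    """
    if not 0.1 <= overlap_fraction <= 0.9:
        raise ValueError("overlap_fraction must be in [0.1, 0.9]")
    h, w = image.shape[:2]
    if n_tiles is None:
        n_tiles = max(2, int(np.ceil(w / 800)))
    if n_tiles <= 1:
        return TileSet([image.copy()], [0])
    tw = int(np.ceil(w / (n_tiles - (n_tiles - 1) * overlap_fraction)))
    if tw >= w:
        warnings.warn("image too small for two tiles; returning it unsplit", stacklevel=2)
        return TileSet([image.copy()], [0])
    stride = int(round(tw * (1 - overlap_fraction)))
    offsets = [min(i * stride, w - tw) for i in range(n_tiles)]
    tiles = [image[:, o:o + tw].copy() for o in offsets]
    return TileSet(tiles, offsets)
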