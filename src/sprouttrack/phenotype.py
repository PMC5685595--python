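"""Tip/stalk phenotype identification, morphometrics and lineage records.

Every branch is headed by exactly one tip cell, so tip count equals branch
count in a sprouting region.  Candidate tips are the ``n_tip`` cells
nearest the end point of a branch's last skeleton segment; among the
candidates, the tip is the one reaching farthest *along the growth
direction*: with s and e the last segment's start and end points and x_i a
candidate position, the projection

    p_i = (e - s) . (x_i - s) / |e - s|

is maximized.  Distance to the end point alone misidentifies laterally
displaced stalk cells; the projection criterion does not.

Region-level morphometrics (branch length, radius, count) are aggregated
into long-format tables and compared across experimental conditions with
one-way ANOVA; p values map onto the conventional significance symbols
(ns, *, **, ***, ****).  Cell positions come from an external cell
tracker as CSV; this module never detects or tracks cells itself.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .branching import BranchRoute

N_TIP_DEFAULT = 3          # tip cell + its two trailing stalk cells
MEMBER_RADIUS_FACTOR = 1.5  # cells within this x local radius belong to a route


# ---------------------------------------------------------------------------
# tip identification

def last_segment_direction(route: BranchRoute) -> tuple[np.ndarray, np.ndarray]:
    """Start and end points of a route's last segment (the piece between
    its final two nodes)."""
    poly = np.asarray(route.polyline, dtype=float)
    end = poly[-1]
    if route.node_positions is not None and len(route.node_positions) >= 2:
        start = np.asarray(route.node_positions[-2], dtype=float)
    else:
        start = poly[0]
    if np.allclose(start, end):
        start = poly[0]
    return start, end


def projection_score(start: np.ndarray, end: np.ndarray, cell: np.ndarray) -> float:
    v_se = end - start
    norm = np.linalg.norm(v_se)
    if norm == 0:
        raise ValueError("degenerate last segment: start equals end")
    return float(v_se @ (cell - start) / norm)


def identify_tip_cell(
    route: BranchRoute,
    cells: pd.DataFrame,
    n_tip: int = N_TIP_DEFAULT,
    near_radius: float | None = None,
    exclude: set | None = None,
) -> tuple[object, float] | None:
    """Tip cell of one branch: (cell_id, projection), or None.

    Candidates are the ``n_tip`` cells nearest the last segment's end
    point (all cells if fewer); the candidate with the largest projection
    onto the segment direction wins, ties breaking toward the smaller
    end-point distance.  Returns None with a warning when no cell lies
    within ``near_radius`` of the end point (default: three times the
    route's mean radius, at least 15 px).
    """
    df = cells if exclude is None else cells[~cells["cell_id"].isin(exclude)]
    if df.empty:
        warnings.warn("no candidate cells for branch", stacklevel=2)
        return None
    start, end = last_segment_direction(route)
    pos = df[["x", "y"]].to_numpy(dtype=float)
    d_end = np.linalg.norm(pos - end, axis=1)
    if near_radius is None:
        r = route.mean_radius if np.isfinite(route.mean_radius) else 5.0
        near_radius = max(3.0 * r, 15.0)
    if d_end.min() > near_radius:
        warnings.warn("no cells near the branch end; no tip assigned", stacklevel=2)
        return None
    order = np.argsort(d_end, kind="stable")[: max(1, n_tip)]
    best, best_key = None, None
    for k in order:
        p = projection_score(start, end, pos[k])
        key = (p, -d_end[k])
        if best_key is None or key > best_key:
            best_key, best = key, k
    return df.iloc[best]["cell_id"], float(best_key[0])


@dataclass
class TipAssignment:
    """Per-branch tip labels for one frame."""

    tips: dict[int, object] = field(default_factory=dict)       # route index -> cell_id
    stalk: dict[int, list] = field(default_factory=dict)        # route index -> stalk cell ids
    unassigned_routes: list[int] = field(default_factory=list)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def table(self, frame: int | None = None) -> pd.DataFrame:
        rows = [
            {"branch": ri, "cell_id": cid, "phenotype": "tip"} for ri, cid in self.tips.items()
        ] + [
            {"branch": ri, "cell_id": cid, "phenotype": "stalk"}
            for ri, cids in self.stalk.items()
            for cid in cids
        ]
        df = pd.DataFrame(rows, columns=["branch", "cell_id", "phenotype"])
        if frame is not None:
            df.insert(0, "frame", frame)
        return df


def route_member_cells(route: BranchRoute, cells: pd.DataFrame,
                       factor: float = MEMBER_RADIUS_FACTOR) -> pd.Index:
    """Cells lying within ``factor`` x the local vessel radius of the route
    polyline (membership, as opposed to tip candidacy)."""
    from .graph import polyline_length, resample_polyline

    pos = cells[["x", "y"]].to_numpy(dtype=float)
    n = max(2, int(np.ceil(polyline_length(route.polyline) / 2.0)) + 1)
    poly = resample_polyline(route.polyline, n)
    r = route.mean_radius if np.isfinite(route.mean_radius) else 5.0
    limit = max(factor * r, 6.0)
    d = np.min(
        np.linalg.norm(pos[:, None, :] - poly[None, :, :], axis=2), axis=1
    )
    return cells.index[d <= limit]


def assign_phenotypes(
    routes: list[BranchRoute],
    cells: pd.DataFrame,
    n_tip: int = N_TIP_DEFAULT,
    near_radius: float | None = None,
) -> TipAssignment:
    """One tip per route; other member cells are stalk.

    When one cell is the top candidate of two routes it goes to the route
    with the larger projection and the other route is re-run without it.
    """
    out = TipAssignment()
    exclusions: dict[int, set] = {i: set() for i in range(len(routes))}
    proposals: dict[int, tuple[object, float]] = {}
    pending = list(range(len(routes)))
    for _ in range(3 * len(routes) + 3):
        for ri in pending:
            res = identify_tip_cell(routes[ri], cells, n_tip, near_radius, exclusions[ri])
            if res is None:
                proposals.pop(ri, None)
            else:
                proposals[ri] = res
        pending = []
        by_cell: dict[object, list[int]] = {}
        for ri, (cid, _) in proposals.items():
            by_cell.setdefault(cid, []).append(ri)
        for cid, ris in by_cell.items():
            if len(ris) > 1:
                winner = max(ris, key=lambda r: (proposals[r][1], -r))
                for r in ris:
                    if r != winner:
                        exclusions[r].add(cid)
                        pending.append(r)
        if not pending:
            break

    taken = set()
    for ri in range(len(routes)):
        if ri in proposals:
            out.tips[ri] = proposals[ri][0]
            taken.add(proposals[ri][0])
        else:
            out.unassigned_routes.append(ri)
    for ri, route in enumerate(routes):
        members = cells.loc[route_member_cells(route, cells), "cell_id"]
        out.stalk[ri] = [c for c in members if c not in taken]
    return out


# ---------------------------------------------------------------------------
# morphometrics and group comparison

def summarize_morphometrics(
    histories: list, conditions: list[str] | None = None, regions: list | None = None
) -> pd.DataFrame:
    """Long-format table of branch length/width and per-region branch count.

    ``histories`` is a list of branch histories (one per sprouting
    region); ``conditions`` labels each region's experimental group.
    """
    if not histories:
        raise ValueError("need at least one history")
    conditions = conditions or ["all"] * len(histories)
    regions = regions or list(range(1, len(histories) + 1))
    rows = []
    for hist, cond, region in zip(histories, conditions, regions):
        per_frame_count: dict[int, int] = {}
        for rec in hist.records.values():
            for f in sorted(rec.routes):
                per_frame_count[f] = per_frame_count.get(f, 0) + 1
                rows.append({
                    "region": region,
                    "condition": cond,
                    "frame": f,
                    "branch_id": rec.branch_id,
                    "length_px": rec.lengths[f],
                    "width_px": rec.widths[f],
                    "radius_px": rec.widths[f] / 2.0,
                })
        for f, n in per_frame_count.items():
            rows.append({
                "region": region, "condition": cond, "frame": f,
                "branch_id": None, "length_px": np.nan, "width_px": np.nan,
                "radius_px": np.nan, "n_branches": n,
            })
    df = pd.DataFrame(rows)
    if "n_branches" not in df:
        df["n_branches"] = np.nan
    return df


def mean_sem(table: pd.DataFrame, metric: str, by: tuple[str, ...] = ("condition", "frame")) -> pd.DataFrame:
    """Mean and standard error of the mean of a metric, per group."""
    d = table.dropna(subset=[metric])
    g = d.groupby(list(by))[metric]
    return g.agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count").reset_index()


def significance_symbol(p: float) -> str:
    """Star convention: ns for p > 0.05, then *, **, ***, **** at the
    0.05, 0.01, 0.001, 0.0001 cutoffs (boundaries inclusive downward)."""
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    if p > 0.0001:
        return "***"
    return "****"


def compare_groups(table: pd.DataFrame, metric: str, group: str = "condition") -> tuple[float, float, str]:
    """One-way ANOVA of ``metric`` across the levels of ``group``.

    Returns (F statistic, p value, significance symbol).
    """
    d = table.dropna(subset=[metric])
    samples = [g[metric].to_numpy(dtype=float) for _, g in d.groupby(group)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two samples")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p), significance_symbol(float(p))


# ---------------------------------------------------------------------------
# lineage records

@dataclass
class LineageRecord:
    frame: int
    cell_id: object
    phenotype: str                  # tip / stalk
    branch_ids: list[int]           # persistent branch ids; >1 => shared trunk
    shared: bool
    monolayer: bool
    parent_id: object | None = None


def build_lineage(
    history,
    frames_routes: list[list[BranchRoute]],
    cell_tables: list[pd.DataFrame],
    assignments: list[TipAssignment],
    monolayer_y: float | None = None,
) -> list[LineageRecord]:
    """Combine branch histories, tip assignments and external cell tracks
    into per-frame lineage records.

    Cells on skeleton shared by several branches get every owning branch id
    and a ``shared`` flag; cells below ``monolayer_y`` are monolayer
    emigrants-to-be.  Parent links are taken from a ``parent_id`` column of
    the cell tables when present — divisions are the external tracker's
    statement, never inferred here.
    """
    records: list[LineageRecord] = []
    for f, (routes, cells, asg) in enumerate(zip(frames_routes, cell_tables, assignments)):
        route_branch = _route_branch_ids(history, f, routes)
        known = set(cells["cell_id"])
        for ri, cid in asg.tips.items():
            if cid not in known:
                raise KeyError(f"tip cell {cid} absent from frame {f} cell table")
        membership: dict[object, list[int]] = {}
        for ri, route in enumerate(routes):
            bid = route_branch.get(ri)
            if bid is None:
                continue
            members = set(cells.loc[route_member_cells(route, cells), "cell_id"])
            members.update(c for r2, c in asg.tips.items() if r2 == ri)
            for cid in members:
                membership.setdefault(cid, []).append(bid)
        tip_cells = {cid: ri for ri, cid in asg.tips.items()}
        for row in cells.itertuples():
            cid = row.cell_id
            bids = sorted(set(membership.get(cid, [])))
            if cid in tip_cells:
                bids = [route_branch.get(tip_cells[cid])] if route_branch.get(tip_cells[cid]) else bids
            mono = bool(monolayer_y is not None and row.y >= monolayer_y)
            records.append(
                LineageRecord(
                    frame=f,
                    cell_id=cid,
                    phenotype="tip" if cid in tip_cells else "stalk",
                    branch_ids=bids,
                    shared=len(bids) > 1,
                    monolayer=mono,
                    parent_id=getattr(row, "parent_id", None),
                )
            )
    return records


def _route_branch_ids(history, frame: int, routes: list[BranchRoute]) -> dict[int, int]:
    """Map route index -> persistent branch id via the history's stored
    node sequences for that frame."""
    by_nodes = {
        tuple(rec.routes[frame]): bid
        for bid, rec in history.records.items()
        if frame in rec.routes
    }
    return {
        ri: by_nodes[tuple(r.nodes)] for ri, r in enumerate(routes) if tuple(r.nodes) in by_nodes
    }


def lineage_to_json(records: list[LineageRecord], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "frame": r.frame,
                    "cell_id": r.cell_id if not hasattr(r.cell_id, "item") else r.cell_id.item(),
                    "phenotype": r.phenotype,
                    "branch_ids": [int(b) for b in r.branch_ids],
                    "shared": r.shared,
                    "monolayer": r.monolayer,
                    "parent_id": None if r.parent_id is None or (isinstance(r.parent_id, float) and np.isnan(r.parent_id)) else int(r.parent_id),
                }
                for r in records
            ],
            fh,
            indent=1,
        )


def plot_lineage(records: list[LineageRecord], ax=None):
    """Frame-by-frame lineage rendering: tip cells red, stalk cells green,
    one ellipse per branch per frame (consistent branch colors), shared
    trunk cells outside the ellipses, monolayer cells under the black line.
    Best effort; the machine-readable records are the contract."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    frames = sorted({r.frame for r in records})
    branch_ids = sorted({b for r in records for b in r.branch_ids})
    cmap = plt.colormaps["tab10"]
    colors = {b: cmap(i % 10) for i, b in enumerate(branch_ids)}

    # vertical layout: one slot per cell id, grouped by first branch
    order = {}
    for r in sorted(records, key=lambda r: (min(r.branch_ids) if r.branch_ids else 99, str(r.cell_id))):
        if r.cell_id not in order:
            order[r.cell_id] = len(order) + (0 if not r.monolayer else 100)
    for r in records:
        y = order[r.cell_id]
        ax.scatter(r.frame, y, c="red" if r.phenotype == "tip" else "green", s=40, zorder=3)
    for f in frames:
        groups: dict[int, list[float]] = {}
        for r in records:
            if r.frame == f and len(r.branch_ids) == 1 and not r.monolayer:
                groups.setdefault(r.branch_ids[0], []).append(order[r.cell_id])
        for b, ys in groups.items():
            cy = (max(ys) + min(ys)) / 2
            h = max(ys) - min(ys) + 0.8
            ax.add_patch(Ellipse((f, cy), 0.55, h, fill=False, color=colors[b], lw=1.5))
    mono_ys = [order[r.cell_id] for r in records if r.monolayer]
    if mono_ys:
        ax.axhline(min(mono_ys) - 0.5, color="black", lw=1.5)
    ax.set_xlabel("frame (day)")
    ax.set_yticks([])
    ax.set_xticks(frames)
    return ax
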