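"""Tip/stalk identification, morphometrics, ANOVA symbols, lineage."""

import numpy as np
import pandas as pd
import pytest

from sprouttrack.branching import BranchRoute
from sprouttrack.phenotype import (
    assign_phenotypes,
    build_lineage,
    compare_groups,
    identify_tip_cell,
    lineage_to_json,
    mean_sem,
    significance_symbol,
    summarize_morphometrics,
)


def straight_route(x=0.0, y0=0.0, y1=10.0, radius=4.0, nodes=(1, 2)):
    poly = np.array([[x, y0], [x, y1]])
    return BranchRoute(nodes=list(nodes), polyline=poly, length=abs(y1 - y0),
                       mean_radius=radius, node_positions=poly.copy())


class TestTipIdentification:
    def test_hand_evaluated_projections(self):
        # growth along +y; projections are simply the y coordinates
        r = straight_route()
        cells = pd.DataFrame({"cell_id": [1, 2, 3], "x": [0, 1, 0], "y": [9.5, 9.0, 8.5]})
        cid, proj = identify_tip_cell(r, cells, n_tip=3)
        assert cid == 1 and proj == pytest.approx(9.5)

    def test_single_cell_is_tip(self):
        r = straight_route()
        cells = pd.DataFrame({"cell_id": ["only"], "x": [0.5], "y": [7.0]})
        cid, _ = identify_tip_cell(r, cells)
        assert cid == "only"

    def test_lateral_trap_projection_beats_distance(self):
        """A lateral cell nearest the end point is not the tip; the cell
        farther ahead along the growth direction is."""
        r = straight_route()
        cells = pd.DataFrame({"cell_id": ["A", "B"], "x": [2.0, 0.0], "y": [9.9, 12.5]})
        d_end = np.hypot(cells.x - 0, cells.y - 10)
        assert d_end["A" == cells.cell_id].iloc[0] < d_end["B" == cells.cell_id].iloc[0]
        cid, _ = identify_tip_cell(r, cells, n_tip=3)
        assert cid == "B"

    def test_no_cells_near_branch_warns(self):
        r = straight_route()
        cells = pd.DataFrame({"cell_id": [1], "x": [500.0], "y": [500.0]})
        with pytest.warns(UserWarning):
            assert identify_tip_cell(r, cells) is None

    @pytest.mark.parametrize("lateral_offset,ahead", [(3.0, 1.5), (4.0, 2.5), (5.0, 3.0)])
    def test_constructed_trap_family(self, lateral_offset, ahead):
        r = straight_route()
        # A: lateral, slightly behind the end point but nearest to it.
        # B: on-axis, ahead of the end point but slightly farther away.
        a = (lateral_offset, 10.0 - 0.5)
        b = (0.0, 10.0 + ahead + lateral_offset * 0.2)
        cells = pd.DataFrame({"cell_id": ["A", "B"], "x": [a[0], b[0]], "y": [a[1], b[1]]})
        cid, _ = identify_tip_cell(r, cells, n_tip=3)
        assert cid == "B"

    def test_agrees_with_distance_when_nearest_is_ahead(self):
        r = straight_route()
        cells = pd.DataFrame({"cell_id": ["near", "far"], "x": [0.2, 1.0], "y": [9.8, 5.0]})
        cid, _ = identify_tip_cell(r, cells)
        assert cid == "near"


class TestAssignPhenotypes:
    def test_three_routes_three_tips(self):
        routes = [straight_route(x=0), straight_route(x=30), straight_route(x=60)]
        cells = pd.DataFrame({
            "cell_id": list(range(6)),
            "x": [0, 0, 30, 30, 60, 60],
            "y": [9.5, 4, 9.5, 4, 9.5, 4],
        })
        asg = assign_phenotypes(routes, cells)
        assert asg.n_tips == 3
        assert len(asg.unassigned_routes) == 0

    def test_one_route_one_tip_rest_stalk(self):
        r = straight_route(y1=60.0)
        cells = pd.DataFrame({"cell_id": list(range(5)), "x": [0] * 5, "y": [58, 45, 30, 15, 5]})
        asg = assign_phenotypes([r], cells)
        assert asg.tips[0] == 0
        assert sorted(asg.stalk[0]) == [1, 2, 3, 4]

    def test_conflict_resolved_by_projection(self):
        # two parallel routes; one cell is top candidate for both
        r1 = straight_route(x=0, y1=20)
        r2 = straight_route(x=6, y1=20)
        cells = pd.DataFrame({"cell_id": ["shared", "other"], "x": [3.0, 6.5], "y": [19.5, 15.0]})
        asg = assign_phenotypes([r1, r2], cells)
        tips = set(asg.tips.values())
        assert len(tips) == 2  # the loser re-ran and took the other cell

    def test_more_routes_than_cells_flags_unfilled(self):
        routes = [straight_route(x=0), straight_route(x=40)]
        cells = pd.DataFrame({"cell_id": [1], "x": [0.0], "y": [9.0]})
        with pytest.warns(UserWarning):
            asg = assign_phenotypes(routes, cells)
        assert asg.unassigned_routes == [1]

    def test_phantom_ground_truth_agreement(self):
        from sprouttrack.phantoms import BranchSpec, PhantomSpec, generate_vessel_mask

        y = BranchSpec(points=[(60, 170), (60, 60)], radius=5,
                       children=[(0.5, BranchSpec(points=[(60, 115), (100, 55)], radius=4))])
        _, gt = generate_vessel_mask(PhantomSpec(image_size=(200, 150), monolayer_height=30, sprouts=[y]))
        f = gt.frame
        routes = []
        for route_nodes in f.routes:
            pos = np.array([[f.graph.nodes[n].x, f.graph.nodes[n].y] for n in route_nodes])
            poly = np.vstack([
                (f.graph.segments[sid].polyline if f.graph.segments[sid].node_a == u
                 else f.graph.segments[sid].polyline[::-1])
                for u, v in zip(route_nodes, route_nodes[1:])
                for sid in [next(s.id for s in f.graph.segments.values()
                                 if {s.node_a, s.node_b} == {u, v})]
            ])
            routes.append(BranchRoute(nodes=route_nodes, polyline=poly,
                                      length=float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()),
                                      mean_radius=5.0, node_positions=pos))
        asg = assign_phenotypes(routes, f.cells)
        true_tips = set(f.cells.loc[f.cells.phenotype == "tip", "cell_id"])
        assert set(asg.tips.values()) == true_tips
        assert asg.n_tips == len(f.routes)


class TestMorphometrics:
    def _history(self, lengths_by_frame):
        from sprouttrack.tracking import BranchHistory

        h = BranchHistory()
        for routes in lengths_by_frame.values():
            break
        bids = {}
        for f, lens in lengths_by_frame.items():
            for i, ln in enumerate(lens):
                r = straight_route(x=30 * i, y1=ln, nodes=(1 + 2 * i, 2 + 2 * i))
                if i not in bids:
                    bids[i] = h.open_branch(f, 1, r)
                else:
                    h.extend_branch(bids[i], f, r)
        return h

    def test_mean_length_single_frame(self):
        h = self._history({0: [100.0, 60.0]})
        t = summarize_morphometrics([h])
        assert t.length_px.dropna().mean() == pytest.approx(80.0)

    def test_condition_ordering_preserved(self):
        ha = self._history({0: [100.0], 1: [120.0]})
        hb = self._history({0: [50.0], 1: [60.0]})
        t = summarize_morphometrics([ha, hb], conditions=["fast", "slow"])
        m = mean_sem(t, "length_px")
        fast = m[m.condition == "fast"].set_index("frame")["mean"]
        slow = m[m.condition == "slow"].set_index("frame")["mean"]
        assert (fast > slow).all()

    def test_branch_count_column(self):
        h = self._history({0: [100.0, 60.0, 40.0]})
        t = summarize_morphometrics([h])
        assert t.n_branches.dropna().tolist() == [3]


class TestAnova:
    def test_symbol_boundaries(self):
        assert significance_symbol(0.2) == "ns"
        assert significance_symbol(0.05) == "*"
        assert significance_symbol(0.03) == "*"
        assert significance_symbol(0.01) == "**"
        assert significance_symbol(0.001) == "***"
        assert significance_symbol(0.0001) == "****"
        assert significance_symbol(1e-7) == "****"

    def test_identical_groups_not_significant(self):
        vals = np.tile(np.arange(10.0), 2)
        t = pd.DataFrame({"condition": ["a"] * 10 + ["b"] * 10, "length_px": vals})
        f, p, sym = compare_groups(t, "length_px")
        assert p > 0.9 and sym == "ns"

    def test_separated_groups_extremely_significant(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({
            "condition": ["a"] * 30 + ["b"] * 30,
            "length_px": np.r_[rng.normal(100, 5, 30), rng.normal(200, 5, 30)],
        })
        f, p, sym = compare_groups(t, "length_px")
        assert p <= 1e-4 and sym == "****"

    def test_undersized_group_rejected(self):
        t = pd.DataFrame({"condition": ["a", "a", "b"], "length_px": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            compare_groups(t, "length_px")


class TestLineage:
    def _setup(self):
        from sprouttrack.tracking import BranchHistory

        h = BranchHistory()
        r0 = straight_route(y1=40, nodes=(1, 2))
        bid = h.open_branch(0, 1, r0)
        r1 = straight_route(y1=70, nodes=(1, 2))
        h.extend_branch(bid, 1, r1)
        cells0 = pd.DataFrame({"cell_id": [10], "x": [0.0], "y": [38.0]})
        cells1 = pd.DataFrame({"cell_id": [10], "x": [0.0], "y": [68.0]})
        asg0 = assign_phenotypes([r0], cells0)
        asg1 = assign_phenotypes([r1], cells1)
        return h, [[r0], [r1]], [cells0, cells1], [asg0, asg1]

    def test_single_cell_always_tip(self):
        h, routes, cells, asgs = self._setup()
        recs = build_lineage(h, routes, cells, asgs)
        assert len(recs) == 2
        assert all(r.phenotype == "tip" for r in recs)
        assert all(r.branch_ids == [1] for r in recs)

    def test_missing_cell_rejected(self):
        h, routes, cells, asgs = self._setup()
        cells[1] = cells[1][cells[1].cell_id != 10]
        with pytest.raises(KeyError):
            build_lineage(h, routes, cells, asgs)

    def test_json_serializable(self, tmp_path):
        h, routes, cells, asgs = self._setup()
        recs = build_lineage(h, routes, cells, asgs, monolayer_y=100.0)
        p = tmp_path / "lineage.json"
        lineage_to_json(recs, p)
        import json

        data = json.loads(p.read_text())
        assert data[0]["phenotype"] == "tip" and data[0]["monolayer"] is False

    def test_stalk_to_tip_transition_at_branch_event(self):
        """When a branch event creates a new route, the cell that becomes
        its head flips from stalk to tip in that frame."""
        from sprouttrack.tracking import BranchHistory

        h = BranchHistory()
        trunk0 = straight_route(y1=60, nodes=(1, 2))
        b1 = h.open_branch(0, 1, trunk0)
        trunk1 = straight_route(y1=90, nodes=(1, 2, 3))
        h.extend_branch(b1, 1, trunk1)
        arm = BranchRoute(nodes=[1, 2, 4], length=90.0, mean_radius=4.0,
                          polyline=np.array([[0.0, 0], [0, 60], [25, 75]]),
                          node_positions=np.array([[0.0, 0], [0, 60], [25, 75]]))
        b2 = h.open_branch(1, 1, arm)

        cells0 = pd.DataFrame({"cell_id": ["t", "s"], "x": [0.0, 0.0], "y": [58.0, 40.0]})
        cells1 = pd.DataFrame({"cell_id": ["t", "s"], "x": [0.0, 24.0], "y": [88.0, 73.0]})
        asg0 = assign_phenotypes([trunk0], cells0)
        asg1 = assign_phenotypes([trunk1, arm], cells1)
        recs = build_lineage(h, [[trunk0], [trunk1, arm]], [cells0, cells1], [asg0, asg1])
        s_phen = {r.frame: r.phenotype for r in recs if r.cell_id == "s"}
        assert s_phen == {0: "stalk", 1: "tip"}
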