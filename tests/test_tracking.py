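"""Hungarian assignment, cost-matrix padding, branch association, history."""

import itertools

import numpy as np
import pytest

from sprouttrack.branching import determine_base_nodes, enumerate_branch_routes, group_sprouts
from sprouttrack.tracking import (
    BranchHistory,
    TrackedFrame,
    associate_branch_nodes,
    associate_sprouts,
    build_cost_matrix,
    solve_assignment,
    track_sequence,
    trajectory_metrics,
)


def frame_from(graph):
    bases, _ = determine_base_nodes(graph)
    routes = enumerate_branch_routes(graph, bases)
    return TrackedFrame(graph, routes, group_sprouts(routes))


class TestCostMatrix:
    def test_distances_and_padding(self):
        cm = build_cost_matrix(np.array([[0, 0]]), np.array([[3, 4], [10, 0]]))
        assert cm.C.tolist() == [[5.0, 10.0]]
        assert cm.P.shape == (2, 2)
        assert cm.c0 > 10.0
        assert (cm.P[1] == cm.c0).all()

    def test_square_case_no_padding(self):
        a = np.array([[0, 0], [5, 5]])
        cm = build_cost_matrix(a, a + 1)
        assert np.array_equal(cm.P, cm.C)

    def test_padding_constant_dominates(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0, 100, (3, 2)), rng.uniform(0, 100, (6, 2))
        cm = build_cost_matrix(a, b)
        assert cm.c0 > cm.C.max()

    def test_retraction_warns_and_transposes(self):
        with pytest.warns(UserWarning):
            cm = build_cost_matrix(np.zeros((3, 2)), np.zeros((1, 2)))
        assert cm.transposed and cm.P.shape == (3, 3)

    def test_symmetric_under_identical_frames(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 50, (4, 2))
        cm = build_cost_matrix(pts, pts)
        assert np.allclose(cm.C, cm.C.T)
        assert np.allclose(np.diag(cm.C), 0)


class TestAssignment:
    def test_zero_diagonal_gives_identity(self):
        P = np.full((4, 4), 9.0)
        np.fill_diagonal(P, 0.0)
        asg = solve_assignment(P)
        assert np.array_equal(asg.Q, np.eye(4, dtype=int))

    def test_row_and_column_sums_are_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(1, 8))
            asg = solve_assignment(rng.uniform(0, 100, (n, n)))
            assert (asg.Q.sum(axis=0) == 1).all() and (asg.Q.sum(axis=1) == 1).all()

    @pytest.mark.parametrize("seed", range(15))
    def test_cost_equals_brute_force_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        P = rng.uniform(0, 100, (n, n))
        best = min(sum(P[i, p[i]] for i in range(n)) for p in itertools.permutations(range(n)))
        assert solve_assignment(P).cost == pytest.approx(best)

    def test_row_column_reduction_invariance(self):
        """Subtracting a constant from any full row/column leaves the
        optimal assignment unchanged."""
        rng = np.random.default_rng(5)
        P = rng.uniform(10, 100, (5, 5))
        base = solve_assignment(P).Q
        P2 = P.copy()
        P2[2, :] -= 7.5
        P2[:, 4] -= 3.25
        assert np.array_equal(solve_assignment(P2).Q, base)

    def test_padded_columns_marked_new(self):
        cm = build_cost_matrix(np.array([[0.0, 0.0]]), np.array([[1.0, 0], [40, 0], [80, 0]]))
        asg = solve_assignment(cm.P, cm.c0)
        assert len(asg.pairs) == 1 and asg.pairs[0] == (0, 0)
        assert asg.new_columns == [1, 2]

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            solve_assignment(np.zeros((2, 3)))


class TestSproutAssociation:
    def _sprouts(self, xs):
        from sprouttrack.branching import Sprout

        return [Sprout(base_node=i + 1, route_indices=[i], mean_x=float(x)) for i, x in enumerate(xs)]

    def test_nearest_matching(self):
        matched, new, term = associate_sprouts(self._sprouts([100, 300]), self._sprouts([105, 310]))
        assert matched == [(0, 0), (1, 1)] and new == [] and term == []

    def test_new_sprout_flagged(self):
        matched, new, term = associate_sprouts(self._sprouts([100]), self._sprouts([102, 290]))
        assert matched == [(0, 0)] and new == [1]

    def test_identity_on_identical_frames(self):
        s = self._sprouts([80, 200, 330])
        matched, new, term = associate_sprouts(s, s)
        assert matched == [(0, 0), (1, 1), (2, 2)] and not new and not term

    def test_termination_warns(self):
        with pytest.warns(UserWarning):
            matched, new, term = associate_sprouts(self._sprouts([100, 300]), self._sprouts([104]))
        assert term == [1] and matched == [(0, 0)]


class TestBranchNodeAssociation:
    def test_printed_two_day_example(self, two_day_frames):
        """Node 2 matches node 2, node 4 is new, segments [2 3]/[2 4]
        correspond, and [4 5], [4 6] are the new branches."""
        day9, day10 = (frame_from(g) for g in two_day_frames)
        assoc = associate_branch_nodes(
            day9.graph, day9.routes, day9.sprouts[0],
            day10.graph, day10.routes, day10.sprouts[0],
        )
        assert assoc.node_pairs == {2: 2}
        assert assoc.new_nodes == [4]
        seg9 = {tuple(sorted((s.node_a, s.node_b))): sid for sid, s in day9.graph.segments.items()}
        seg10 = {tuple(sorted((s.node_a, s.node_b))): sid for sid, s in day10.graph.segments.items()}
        assert assoc.segment_pairs[seg9[(2, 3)]] == seg10[(2, 3)]
        assert assoc.segment_pairs[seg9[(2, 4)]] == seg10[(2, 4)]
        assert set(assoc.new_segments) == {seg10[(4, 5)], seg10[(4, 6)]}

    def test_identity_on_identical_frames(self, two_day_frames):
        day9, _ = two_day_frames
        f = frame_from(day9)
        f2 = frame_from(day9.copy())
        assoc = associate_branch_nodes(f.graph, f.routes, f.sprouts[0],
                                       f2.graph, f2.routes, f2.sprouts[0])
        assert assoc.node_pairs == {2: 2} and not assoc.new_nodes and not assoc.new_segments


class TestHistory:
    def test_printed_two_day_history_table(self, two_day_frames):
        frames = [frame_from(g) for g in two_day_frames]
        hist = track_sequence(frames)
        t = hist.table()
        assert t.loc[1].tolist() == ["1 2 3", "1 2 3"]
        assert t.loc[2].tolist() == ["1 2 4", "1 2 4 5"]
        assert t.loc[3].tolist() == ["", "1 2 4 6"]
        assert hist.records[3].birth_frame == 1

    def test_single_frame_all_born_at_zero(self, two_sprout_graph):
        hist = track_sequence([frame_from(two_sprout_graph)])
        assert len(hist.records) == 4
        assert all(r.birth_frame == 0 for r in hist.records.values())

    def test_unknown_branch_extension_rejected(self):
        with pytest.raises(KeyError):
            BranchHistory().extend_branch(99, 1, None)

    def test_scripted_phantom_birth_frames(self):
        from sprouttrack.phantoms import BranchSpec, PhantomSpec, TimelapseSpec, generate_timelapse
        from sprouttrack.pipeline import analyze_mask_sequence
        from sprouttrack.skeletonize import SkelConfig

        pspec = PhantomSpec(
            image_size=(260, 320), monolayer_height=36,
            sprouts=[BranchSpec(points=[(90, 224), (92, 180)], radius=6),
                     BranchSpec(points=[(230, 224), (228, 180)], radius=6)],
        )
        tspec = TimelapseSpec(n_frames=6, elongation_per_frame=28,
                              branching_events=[(2, 1, -40), (3, 2, 40)], seed=3)
        masks, gt = generate_timelapse(pspec, tspec)
        cropped = [pspec.crop_to_gel(m) for m in masks]
        frames, hist = analyze_mask_sequence(cropped, SkelConfig(u_threshold=15))
        births = sorted(r.birth_frame for r in hist.records.values())
        assert births == [0, 0, 2, 3]

    def test_route_lengths_nondecreasing_under_elongation(self):
        from sprouttrack.phantoms import BranchSpec, PhantomSpec, TimelapseSpec, generate_timelapse
        from sprouttrack.pipeline import analyze_mask_sequence
        from sprouttrack.skeletonize import SkelConfig

        pspec = PhantomSpec(image_size=(260, 200), monolayer_height=36,
                            sprouts=[BranchSpec(points=[(100, 224), (98, 180)], radius=6)])
        masks, _ = generate_timelapse(pspec, TimelapseSpec(n_frames=5, elongation_per_frame=30, seed=1))
        cropped = [pspec.crop_to_gel(m) for m in masks]
        _, hist = analyze_mask_sequence(cropped, SkelConfig(u_threshold=15))
        rec = hist.records[1]
        lens = [rec.lengths[f] for f in sorted(rec.lengths)]
        assert all(b >= a - 2.0 for a, b in zip(lens, lens[1:]))


class TestTrajectoryMetrics:
    def test_perfect_match(self):
        hist = BranchHistory()
        from sprouttrack.branching import BranchRoute

        r = BranchRoute(nodes=[1, 2], polyline=np.array([[0.0, 10.0], [0.0, 0.0]]),
                        length=10.0, mean_radius=3.0)
        bid = hist.open_branch(0, 1, r)
        hist.extend_branch(bid, 1, r)
        truth = {7: {0: (0.0, 0.0), 1: (0.0, 0.0)}}
        m = trajectory_metrics(hist, truth, tolerance=5)
        assert m["precision"] == 1.0 and m["recall"] == 1.0

    def test_birth_frame_mismatch_fails(self):
        hist = BranchHistory()
        from sprouttrack.branching import BranchRoute

        r = BranchRoute(nodes=[1, 2], polyline=np.array([[0.0, 10.0], [0.0, 0.0]]),
                        length=10.0, mean_radius=3.0)
        hist.open_branch(3, 1, r)
        truth = {7: {0: (0.0, 0.0), 1: (0.0, 0.0), 2: (0.0, 0.0), 3: (0.0, 0.0)}}
        m = trajectory_metrics(hist, truth, tolerance=5)
        assert m["matched"] == 0
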