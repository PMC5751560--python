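"""Extractor internals: initialisation, candidates, closedness, reduction,
and full recovery on shapes with known vertices."""

import numpy as np
import pytest

from kdomseg import synth
from kdomseg.geometry import PointSet, confidence_length
from kdomseg.kdp import (
    ExtractionConfig,
    balance_ratio,
    best_slot,
    candidates,
    extract,
    extract_with_stats,
    farthest_pair,
    insert,
    reduce_point_set,
    select_candidate,
    simplify,
    sum_distance_scores,
)
from kdomseg.kdp import test_closedness as closedness_of
from kdomseg.sequence import CandidateInsertion, DominantSequence, Measure

from conftest import brute_force_farthest, brute_force_scores


class TestFarthestPair:
    def test_square_diagonal(self):
        P = PointSet([[0, 0], [1, 0], [1, 1], [0, 1]])
        a, b = farthest_pair(P)
        assert np.linalg.norm(a - b) == pytest.approx(np.sqrt(2))

    def test_ellipse_extremes(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        P = PointSet(np.column_stack([10 * np.cos(t), 3 * np.sin(t)]))
        a, b = farthest_pair(P)
        assert np.linalg.norm(a - b) == pytest.approx(20.0, abs=0.01)
        assert {round(a[0]), round(b[0])} == {10, -10}

    def test_two_points(self):
        P = PointSet([[0, 0], [5, 5]])
        a, b = farthest_pair(P)
        assert np.allclose(sorted([tuple(a), tuple(b)]), [[0, 0], [5, 5]])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            farthest_pair(PointSet([[1, 2]]))

    @pytest.mark.parametrize("n", [10, 100, 500])
    def test_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        pts = rng.uniform(0, 100, size=(n, 2))
        P = PointSet(pts)
        a, b = farthest_pair(P)
        i, j = brute_force_farthest(P.coords)
        assert np.allclose(np.sort([a, b], axis=0),
                           np.sort([P.coords[i], P.coords[j]], axis=0))


class TestSumDistanceScores:
    def test_single_point(self):
        seq = DominantSequence([[3.0, 4.0], [0.0, 0.0]])
        f = sum_distance_scores(PointSet([[0.0, 0.0]]), seq)
        assert f[0] == pytest.approx(5.0)

    def test_empty_set(self):
        seq = DominantSequence([[0.0, 0.0], [1.0, 0.0]])
        assert sum_distance_scores(PointSet([]), seq).size == 0

    def test_order_statistics_match_brute_force(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 50, size=(300, 2))
        seq = DominantSequence(rng.uniform(0, 50, size=(5, 2)))
        f = sum_distance_scores(PointSet(pts), seq)
        g = brute_force_scores(PointSet(pts).coords, seq.vertices)
        assert np.argmax(f) == np.argmax(g)
        assert np.argmin(f) == np.argmin(g)
        assert np.allclose(f, g)


class TestSlotAndSelection:
    def test_fourth_corner_slot(self):
        # square corner d belongs between c and a in <a, b, c>
        seq = DominantSequence([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        slot, conf = best_slot(seq, [0.0, 1.0], "length")
        assert slot == 2
        assert conf == pytest.approx(4.0)  # the completed unit square

    def test_single_open_pair_is_forced(self):
        seq = DominantSequence([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]],
                               [True, False, True])
        slot, _ = best_slot(seq, [2.0, 0.5], "length")
        assert slot == 1

    def test_terminal_sequence_raises(self):
        seq = DominantSequence([[0.0, 0.0], [1.0, 0.0]], [True, True])
        with pytest.raises(ValueError):
            best_slot(seq, [0.5, 0.1], "length")

    def test_count_mode_prefers_supported_slot(self, rectangle_points):
        P, corners = rectangle_points
        seq = DominantSequence(corners[[0, 1, 2]])
        slot, conf = best_slot(seq, corners[3], "count", P)
        assert slot == 2
        assert conf == len(P)  # completed rectangle covers every point

    @pytest.mark.parametrize(
        "v, a, b, expected",
        [((0.5, 0.5), (0.0, 0.5), (1.0, 0.5), 1.0),
         ((1.0, 0.0), (0.0, 0.0), (5.0, 0.0), 0.25),
         ((0.0, 0.0), (0.0, 0.0), (1.0, 0.0), 0.0)],  # endpoint: never chosen
    )
    def test_balance_ratio(self, v, a, b, expected):
        seq = DominantSequence([list(a), list(b)])
        assert balance_ratio(v, seq, 0) == pytest.approx(expected)

    def test_select_highest_ratio(self):
        mk = lambda m, r: CandidateInsertion(np.zeros(2) + r, m, 0, 0.0, r)
        assert select_candidate([mk(Measure.MAX, 0.9), mk(Measure.MIN, 0.4)]).measure is Measure.MAX
        assert select_candidate([mk(Measure.MAX, 0.2), mk(Measure.MIN, 0.2)]).measure is Measure.MAX
        assert select_candidate(
            [mk(Measure.MAX, 0.1), mk(Measure.MIN, 0.2), mk(Measure.MEDIAN, 0.7)]
        ).measure is Measure.MEDIAN

    def test_candidates_cover_requested_measures(self):
        rng = np.random.default_rng(1)
        P = PointSet(rng.uniform(0, 40, size=(60, 2)))
        seq = DominantSequence([[0.0, 0.0], [40.0, 40.0]])
        cands = candidates(P, seq, "max_min_median")
        assert {c.measure for c in cands} <= {Measure.MAX, Measure.MIN, Measure.MEDIAN}
        assert any(c.measure is Measure.MAX for c in cands)
        for c in cands:
            assert 0.0 <= c.ratio <= 1.0
        only_max = candidates(P, seq, "max_only")
        assert [c.measure for c in only_max] == [Measure.MAX]
        assert candidates(PointSet([]), seq) == []


class TestInsertAndClosedTags:
    def test_rectangle_walkthrough(self, rectangle_points):
        """Third point closes its two true edges, fourth closes the rest."""
        P, corners = rectangle_points
        v1, v2 = farthest_pair(P)  # a diagonal pair
        seq = DominantSequence([v1, v2])
        f = sum_distance_scores(P.difference(seq.vertices), seq)
        v3 = P.difference(seq.vertices).coords[np.argmax(f)]
        slot, _ = best_slot(seq, v3, "length")
        cand = CandidateInsertion(v3, Measure.MAX, slot, 0.0,
                                  balance_ratio(v3, seq, slot))
        seq3 = insert(seq, cand, P)
        assert sorted(seq3.closed) == [False, True, True]
        # fourth corner into the remaining open slot -> fully closed
        open_slot = seq3.open_pair_indices()[0]
        remaining = P.difference(seq3.vertices)
        f4 = sum_distance_scores(remaining, seq3)
        v4 = remaining.coords[np.argmax(f4)]
        cand4 = CandidateInsertion(v4, Measure.MAX, open_slot, 0.0,
                                   balance_ratio(v4, seq3, open_slot))
        seq4 = insert(seq3, cand4, P)
        assert seq4.all_closed
        d = np.linalg.norm(seq4.vertices[:, None] - corners[None], axis=2)
        assert d.min(axis=1).max() < 1.5

    def test_insert_into_closed_pair_rejected(self):
        seq = DominantSequence([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]],
                               [True, False, False])
        cand = CandidateInsertion(np.array([0.5, -0.1]), Measure.MAX, 0, 0.0, 0.9)
        with pytest.raises(ValueError):
            insert(seq, cand)

    def test_length_confidence_never_decreases(self, unit_square_seq):
        cand = CandidateInsertion(np.array([0.5, -0.6]), Measure.MAX, 0, 0.0, 0.8)
        assert confidence_length(insert(unit_square_seq, cand)) >= \
            confidence_length(unit_square_seq)


class TestClosedness:
    def test_dense_chain_closes_and_removes(self):
        v, w = np.array([0.0, 0.0]), np.array([50.0, 0.0])
        chain = np.column_stack([np.arange(1, 50, 1.0), np.zeros(49)])
        extra = np.array([[25.0, 30.0], [10.0, -20.0]])
        P = PointSet(np.vstack([chain, extra]))
        closed, reduced = closedness_of(v, w, P, eps=0.02, gap_tol=3.0)
        assert closed
        assert len(reduced) == 2  # only the far points survive

    def test_half_covered_stays_open(self):
        v, w = np.array([0.0, 0.0]), np.array([50.0, 0.0])
        half = np.column_stack([np.arange(1, 25, 1.0), np.zeros(24)])
        P = PointSet(half)
        closed, reduced = closedness_of(v, w, P, eps=0.02, gap_tol=3.0)
        assert not closed
        assert len(reduced) == len(P)

    def test_empty_set_open(self):
        closed, P = closedness_of([0, 0], [1, 0], PointSet([]))
        assert not closed and len(P) == 0


class TestReduce:
    def test_two_open_pairs_two_subsets(self, rectangle_points):
        P, corners = rectangle_points
        seq = DominantSequence(corners, [True, False, True, False])
        subsets, removed = reduce_point_set(P, seq, 0.02, 4.0)
        assert [i for _, i in subsets] == [1, 3]
        assert len(subsets) == 2

    def test_conservation(self, rectangle_points):
        P, corners = rectangle_points
        seq = DominantSequence(corners, [True, False, True, False])
        subsets, removed = reduce_point_set(P, seq, 0.02, 4.0)
        assert sum(len(s) for s, _ in subsets) + len(removed) == len(P)

    def test_all_closed_terminal(self, rectangle_points):
        P, corners = rectangle_points
        seq = DominantSequence(corners, [True] * 4)
        subsets, removed = reduce_point_set(P, seq, 0.02, 4.0)
        assert subsets == []
        assert len(removed) == len(P)

    def test_single_open_pair_collects_everything(self, rectangle_points):
        P, corners = rectangle_points
        seq = DominantSequence(corners, [True, True, True, False])
        subsets, removed = reduce_point_set(P, seq, 0.02, 4.0)
        assert len(subsets) == 1
        assert subsets[0][1] == 3


class TestSimplify:
    def test_removes_collinear_vertex(self):
        seq = DominantSequence([[0.0, 0.0], [50.0, 0.3], [100.0, 0.0],
                                [100.0, 60.0], [0.0, 60.0]])
        out = simplify(seq, eps=0.02)
        assert len(out) == 4

    def test_keeps_genuine_corners(self, unit_square_seq):
        big = DominantSequence(unit_square_seq.vertices * 100)
        assert len(simplify(big, eps=0.02)) == 4


class TestExtract:
    def test_rectangle_recovery(self, rectangle_points):
        P, corners = rectangle_points
        seq = extract(P)
        assert len(seq) == 4
        d = np.linalg.norm(seq.vertices[:, None] - corners[None], axis=2)
        assert d.min(axis=1).max() < 1.5

    def test_hexagon_recovery(self):
        spec = synth.regular_polygon_spec(6, seed=11, jitter=0.0, perturb=0.0)
        P, truth = synth.sample_boundary(spec)
        seq = extract(P)
        assert len(seq) == 6
        d = np.linalg.norm(seq.vertices[:, None] - truth.vertices[None], axis=2)
        assert d.min(axis=1).max() < 1.5

    def test_l_shape_exercises_reduction(self):
        spec = synth.l_shape_spec(seed=4)
        P, truth = synth.sample_boundary(spec)
        seq, stats = extract_with_stats(P)
        assert len(seq) == 6
        assert stats.reductions >= 1
        d = np.linalg.norm(seq.vertices[:, None] - truth.vertices[None], axis=2)
        assert d.min(axis=1).max() < 2.0

    def test_max_only_equals_full_on_convex(self):
        spec = synth.regular_polygon_spec(5, seed=21)
        P, _ = synth.sample_boundary(spec)
        full = extract(P, ExtractionConfig(measure_mode="max_min_median"))
        max_only = extract(P, ExtractionConfig(measure_mode="max_only"))
        assert len(full) == len(max_only) == 5
        d = np.linalg.norm(full.vertices[:, None] - max_only.vertices[None], axis=2)
        assert d.min(axis=1).max() < 1e-6

    def test_tiny_set_returns_farthest_pair(self):
        seq = extract(PointSet([[0, 0], [1, 1], [2, 0]]))
        assert len(seq) == 2
        assert np.linalg.norm(seq.vertices[0] - seq.vertices[1]) == pytest.approx(2.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            extract(PointSet([[0, 0]]))

    def test_deterministic(self):
        spec = synth.regular_polygon_spec(7, seed=3)
        P, _ = synth.sample_boundary(spec)
        s1 = extract(P)
        s2 = extract(PointSet(P.coords.copy()))
        assert np.array_equal(s1.vertices, s2.vertices)
        assert s1.closed == s2.closed
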