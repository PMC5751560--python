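"""Geometric primitives: sum distances, bands, confidences, Fermat point."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdomseg.geometry import (
    PointSet,
    Segment,
    confidence_count,
    confidence_length,
    fermat_point,
    is_insertable,
    point_segment_sum_distance,
    vertex_angle,
)
from kdomseg.sequence import DominantSequence

from conftest import fermat_grid_oracle

coord = st.floats(-50, 50, allow_nan=False, allow_infinity=False)
point = st.tuples(coord, coord)


class TestPointSegmentSumDistance:
    @pytest.mark.parametrize(
        "p, a, b, expected",
        [
            ((0, 1), (-1, 0), (1, 0), 2 * np.sqrt(2)),
            ((1, 0), (0, 0), (2, 0), 2.0),  # interior point: equals length
            ((3, 4), (0, 0), (3, 0), 9.0),  # 5 to one end, 4 to the other
        ],
    )
    def test_examples(self, p, a, b, expected):
        assert point_segment_sum_distance(p, Segment(np.array(a), np.array(b))) == pytest.approx(expected)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError):
            Segment(np.array([0.0, 0.0]), np.array([0.0, 1e-12]))

    @settings(derandomize=True, max_examples=200)
    @given(p=point, a=point, b=point)
    def test_lower_bound_is_segment_length(self, p, a, b):
        if np.hypot(a[0] - b[0], a[1] - b[1]) < 1e-6:
            return
        s = Segment(np.array(a, float), np.array(b, float))
        assert point_segment_sum_distance(p, s) >= s.length - 1e-9

    def test_equality_iff_on_segment(self):
        s = Segment(np.array([0.0, 0.0]), np.array([4.0, 0.0]))
        for t in np.linspace(0, 1, 9):
            p = np.array([4 * t, 0.0])
            assert point_segment_sum_distance(p, s) == pytest.approx(s.length)
        assert point_segment_sum_distance([2.0, 0.5], s) > s.length + 0.1


class TestInsertability:
    def test_collinear_point_at_zero_eps(self):
        seq = DominantSequence([[0.0, 0.0], [2.0, 0.0]])
        assert is_insertable([1.0, 0.0], seq, eps=0.0)

    def test_far_point_rejected(self):
        seq = DominantSequence([[0.0, 0.0], [2.0, 0.0]])
        assert not is_insertable([1.0, 10.0], seq, eps=0.02)

    def test_near_band_boundary(self):
        # 2*sqrt(1.01) ~ 2.00998 <= 1.02 * 2
        seq = DominantSequence([[0.0, 0.0], [2.0, 0.0]])
        assert is_insertable([1.0, 0.1], seq, eps=0.02)

    def test_closed_pairs_excluded(self):
        seq = DominantSequence([[0.0, 0.0], [2.0, 0.0]], [True, True])
        assert not is_insertable([1.0, 0.0], seq, eps=0.02)

    def test_too_small_sequence_rejected(self):
        with pytest.raises(ValueError):
            DominantSequence([[0.0, 0.0]])

    @settings(derandomize=True, max_examples=100)
    @given(p=point, e1=st.floats(0, 0.05), e2=st.floats(0, 0.05))
    def test_monotone_in_eps(self, p, e1, e2):
        seq = DominantSequence([[0.0, 0.0], [10.0, 3.0], [4.0, 9.0]])
        lo, hi = sorted([e1, e2])
        if is_insertable(p, seq, lo):
            assert is_insertable(p, seq, hi)


class TestConfidences:
    def test_count_points_on_square_edges(self, unit_square_seq):
        on_edges = [(0.25, 0.0), (0.5, 0.0), (1.0, 0.3), (1.0, 0.9),
                    (0.7, 1.0), (0.2, 1.0), (0.0, 0.6), (0.0, 0.1),
                    (0.0, 0.0), (1.0, 1.0)]
        C = PointSet(on_edges)
        assert confidence_count(unit_square_seq, C, tol=0.0) == 10
        far = [(5.0, 5.0), (-3.0, 2.0), (0.5, 0.5), (9.0, 0.0), (0.5, -4.0)]
        C2 = PointSet(on_edges + far)
        assert confidence_count(unit_square_seq, C2, tol=0.02) == 10

    def test_count_empty_set(self, unit_square_seq):
        assert confidence_count(unit_square_seq, PointSet([]), 0.02) == 0

    def test_length_of_square_perimeter(self, unit_square_seq):
        assert confidence_length(unit_square_seq) == pytest.approx(4.0)

    def test_length_two_points_out_and_back(self):
        seq = DominantSequence([[0.0, 0.0], [3.0, 4.0]])
        assert confidence_length(seq) == pytest.approx(10.0)

    def test_repeated_vertex_rejected_at_construction(self):
        with pytest.raises(ValueError):
            DominantSequence([[0.0, 0.0], [1.0, 0.0], [0.0, 0.0]])

    def test_insertion_increases_length_by_detour(self, unit_square_seq):
        v = np.array([0.5, -0.8])
        before = confidence_length(unit_square_seq)
        after = confidence_length(unit_square_seq.with_insertion(v, 0))
        detour = (np.linalg.norm(v - [0, 0]) + np.linalg.norm(v - [1, 0]) - 1.0)
        assert after - before == pytest.approx(detour)
        assert after >= before


class TestFermatPoint:
    def test_equilateral_centroid(self):
        t = np.array([[1.0, 0.0],
                      [-0.5, np.sqrt(3) / 2],
                      [-0.5, -np.sqrt(3) / 2]])
        assert np.allclose(fermat_point(*t), [0.0, 0.0], atol=1e-9)

    def test_obtuse_vertex_rule(self):
        # ~150 degree angle at a
        a, b, c = [0.0, 0.0], [4.0, 0.0], [-3.9, 1.0]
        ang = vertex_angle(b, a, c)
        assert ang > 2 * np.pi / 3
        assert np.allclose(fermat_point(a, b, c), a)

    def test_matches_grid_oracle(self):
        a, b, c = [0.0, 0.0], [4.0, 0.0], [2.0, 3.0]
        # coarse grid here keeps the unit test fast; the acceptance suite
        # runs the full-resolution comparison over many triangles
        expect = fermat_grid_oracle(a, b, c, step=2e-3)
        assert np.linalg.norm(fermat_point(a, b, c) - expect) < 4e-3

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            fermat_point([0, 0], [1, 1], [2, 2])


class TestVertexAngle:
    @pytest.mark.parametrize(
        "prev, v, nxt, expected",
        [
            ((0, 1), (0, 0), (1, 0), np.pi / 2),
            ((-1, 0), (0, 0), (1, 0), np.pi),
            ((1, 0.1), (0, 0), (1, -0.1), 0.19933730),
        ],
    )
    def test_examples(self, prev, v, nxt, expected):
        assert vertex_angle(prev, v, nxt) == pytest.approx(expected, abs=1e-6)

    def test_coincident_rejected(self):
        with pytest.raises(ValueError):
            vertex_angle([0, 0], [0, 0], [1, 0])

    @settings(derandomize=True, max_examples=100)
    @given(a=point, b=point, c=point)
    def test_symmetric_in_neighbours(self, a, b, c):
        pa, pb, pc = (np.array(x, float) for x in (a, b, c))
        if min(np.linalg.norm(pa - pb), np.linalg.norm(pc - pb)) < 1e-6:
            return
        assert vertex_angle(pa, pb, pc) == pytest.approx(vertex_angle(pc, pb, pa))


class TestPointSet:
    def test_duplicates_collapsed(self):
        P = PointSet([[0, 0], [1, 1], [0, 0], [1, 1], [2, 2]])
        assert len(P) == 3

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            PointSet([[0, np.nan]])

    def test_difference_removes_exact_rows(self):
        P = PointSet([[0, 0], [1, 1], [2, 2]])
        Q = P.difference(np.array([[1.0, 1.0]]))
        assert len(Q) == 2
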