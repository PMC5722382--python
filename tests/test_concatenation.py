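"""The concatenation algorithm: chord geometry, splicing, iteration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafknot import concatenation as cc
from leafknot.topology import Junction, JunctionKind
from leafknot.tracing import Contour, ContourSet, RegionClass, signed_area


def shapely_segments_intersect(a1, b2, a2, b1):
    """Independent oracle: shapely intersection of the two closed chords."""
    from shapely.geometry import LineString

    return LineString([a1, b2]).intersects(LineString([a2, b1]))


def _contour(points, label="c", cls=RegionClass.OTHER):
    return Contour(np.asarray(points, float), label=label, region_class=cls)


class TestNeighborPoints:
    @pytest.mark.parametrize(
        "n, i, expected", [(5, 0, (4, 1)), (5, 4, (3, 0)), (3, 1, (0, 2))]
    )
    def test_modular_wrap(self, n, i, expected):
        c = _contour(np.arange(2 * n).reshape(n, 2))
        assert cc.neighbor_points(c, i) == expected

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            cc.neighbor_points(_contour([[0, 0], [1, 1]]), 0)


class TestBuildSegmentPair:
    def test_symmetric_x_crossing_evaluates_by_hand(self):
        # a1=(0,0) b2=(2,2): slope 1, intercept 0; a2=(0,2) b1=(2,0): slope -1,
        # intercept 2; Z=(1,1) inside the common range
        a = _contour([[0, 0], [0, 1], [0, 2]])
        b = _contour([[2, 0], [2, 1], [2, 2]])
        sp = cc.build_segment_pair(a, b, 1, 1)
        assert sp.a1 == (0.0, 0.0) and sp.b2 == (2.0, 2.0)
        assert sp.a2 == (0.0, 2.0) and sp.b1 == (2.0, 0.0)
        assert sp.p_slope == pytest.approx(1.0)
        assert sp.p_intercept == pytest.approx(0.0)
        assert sp.q_slope == pytest.approx(-1.0)
        assert sp.q_intercept == pytest.approx(2.0)
        assert sp.Z == pytest.approx((1.0, 1.0))
        assert sp.intersects

    def test_parallel_chords_do_not_intersect(self):
        a = _contour([[0, 0], [0.5, 1.5], [0, 3]])  # a1=(0,0), a2=(0,3)
        b = _contour([[1, 4], [1.5, 2.5], [1, 1]])  # b1=(1,4), b2=(1,1)
        sp = cc.build_segment_pair(a, b, 1, 1)
        assert sp.p_slope == pytest.approx(sp.q_slope)  # both slope 1
        assert not sp.intersects and sp.Z is None

    def test_vertical_chord_uses_exact_predicate(self):
        a = _contour([[1, 0], [0, 1], [1, 2]])   # p: (1,0)-(1,2) is vertical
        b = _contour([[3, 2], [2, 1], [1, 2]])
        sp = cc.build_segment_pair(a, b, 1, 1)
        assert sp.used_fallback
        assert sp.intersects == shapely_segments_intersect(sp.a1, sp.b2, sp.a2, sp.b1)

    def test_agrees_with_shapely_on_random_pairs(self, rng):
        mismatches = 0
        for _ in range(2000):
            pts = rng.uniform(0, 100, (6, 2))
            a = _contour(pts[:3])
            b = _contour(pts[3:])
            sp = cc.build_segment_pair(a, b, 1, 1)
            if sp.intersects != shapely_segments_intersect(sp.a1, sp.b2, sp.a2, sp.b1):
                mismatches += 1
        assert mismatches == 0


class TestOrientForJunction:
    def _junction(self, kind, a="a", b="b"):
        return Junction(kind, (1.0, 1.0), a, b, 1, 1, 2.0)

    def _pair(self, b_up=True):
        # two vertical 3-vertex chains 2 px apart; both ascending <=> chords cross
        a = _contour([[0, 0], [0, 1], [0, 2]], label="a")
        if b_up:
            b = _contour([[2, 0], [2, 1], [2, 2]], label="b")
        else:
            b = _contour([[2, 2], [2, 1], [2, 0]], label="b")
        return a, b

    def test_cross_junction_already_intersecting_is_noop(self):
        a, b = self._pair(b_up=True)
        a2, b2, a_c, b_c, sp = cc.orient_for_junction(a, b, self._junction(JunctionKind.CROSS))
        assert b2 is b and sp.intersects and (a_c, b_c) == (1, 1)

    def test_cross_junction_fixed_by_reversing_b(self):
        a, b = self._pair(b_up=False)
        _, b2, _, b_c, sp = cc.orient_for_junction(a, b, self._junction(JunctionKind.CROSS))
        assert b2 is not b and sp.intersects
        assert np.array_equal(b2.vertices[b_c], b.vertices[1])

    def test_touch_junction_fixed_by_reversing_b(self):
        a, b = self._pair(b_up=True)
        _, b2, _, _, sp = cc.orient_for_junction(a, b, self._junction(JunctionKind.TOUCH))
        assert b2 is not b and not sp.intersects

    def test_touch_junction_already_disjoint_is_noop(self):
        a, b = self._pair(b_up=False)
        _, b2, _, _, sp = cc.orient_for_junction(a, b, self._junction(JunctionKind.TOUCH))
        assert b2 is b and not sp.intersects


class TestSplice:
    def test_hand_traced_square_plus_triangle(self):
        # A: 4-vertex square opened at a_c=0; B: 3-vertex triangle at b_c=0
        A = _contour([[0, 0], [4, 0], [4, 4], [0, 4]], label="A")
        B = _contour([[10, 0], [14, 0], [12, 3]], label="B")
        merged = cc.splice(A, B, 0, 0)
        expected = np.array(
            [
                [0, 0],            # a_c opens
                [10, 0], [14, 0], [12, 3],  # full tour of B from b_c
                [10, 0],           # b_c again
                [0, 0],            # back to a_c
                [4, 0], [4, 4], [0, 4],     # rest of A
            ],
            float,
        )
        assert np.array_equal(merged.vertices, expected)
        assert merged.n == A.n + B.n + 2

    def test_interior_junction_indices(self):
        A = _contour([[0, 0], [4, 0], [4, 4], [0, 4]], label="A")
        B = _contour([[10, 0], [14, 0], [12, 3]], label="B")
        merged = cc.splice(A, B, 2, 1)
        expected = np.array(
            [[4, 4], [14, 0], [12, 3], [10, 0], [14, 0], [4, 4], [0, 4], [0, 0], [4, 0]],
            float,
        )
        assert np.array_equal(merged.vertices, expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_vertex_multiset_conservation(self, seed):
        r = np.random.default_rng(seed)
        na, nb = int(r.integers(3, 12)), int(r.integers(3, 12))
        A = _contour(r.uniform(0, 50, (na, 2)), label="A")
        B = _contour(r.uniform(0, 50, (nb, 2)), label="B")
        a_c, b_c = int(r.integers(na)), int(r.integers(nb))
        merged = cc.splice(A, B, a_c, b_c)
        assert merged.n == na + nb + 2
        combined = np.vstack(
            [A.vertices, B.vertices, A.vertices[a_c : a_c + 1], B.vertices[b_c : b_c + 1]]
        )
        assert np.array_equal(
            np.sort(merged.vertices, axis=0), np.sort(combined, axis=0)
        )


class TestConcatenateAll:
    def test_single_contour_without_junctions_is_returned(self):
        ring = _contour([[0, 0], [5, 0], [5, 5], [0, 5]], label="only")
        cset = ContourSet(contours=[ring], source_shape=(10, 10))
        out = cc.concatenate_all(cset, [])
        assert np.array_equal(out.vertices, ring.vertices)

    def test_ledger_decrements_by_one_per_merge(self, fig1d_result):
        log = fig1d_result.merge_log
        effective = [r for r in log if not r.skipped]
        assert len(effective) == len(fig1d_result.contours) - 1
        for rec in effective:
            assert rec.contours_after == rec.contours_before - 1
        assert effective[-1].contours_after == 1

    def test_final_vertex_count_matches_merge_arithmetic(self, fig1d_result):
        merges = sum(1 for r in fig1d_result.merge_log if not r.skipped)
        total = sum(c.n for c in fig1d_result.contours)
        assert fig1d_result.final_contour.n == total + 2 * merges

    def test_disconnected_junction_graph_raises(self):
        a = _contour([[0, 0], [5, 0], [5, 5]], label="a")
        b = _contour([[20, 20], [25, 20], [25, 25]], label="b")
        cset = ContourSet(contours=[a, b], source_shape=(30, 30))
        with pytest.raises(ValueError):
            cc.concatenate_all(cset, [])

    def test_two_runs_are_byte_identical(self, fig1d):
        from leafknot import pipeline

        image, _ = fig1d
        r1 = pipeline.run_pipeline(image)
        r2 = pipeline.run_pipeline(image)
        assert np.array_equal(r1.final_contour.vertices, r2.final_contour.vertices)
        assert r1.final_contour.vertices.tobytes() == r2.final_contour.vertices.tobytes()


class TestLocalCrossingNumber:
    def test_plain_x_crossing_counts_one(self):
        # a figure-eight-like ring crossing once near the origin
        ring = np.array(
            [[-10, -1], [10, 1], [10, 8], [-10, 8], [-10, 1], [10, -1], [10, -8], [-10, -8]],
            float,
        )
        assert cc.local_crossing_number(ring, (0.0, 0.0), 5.0) == 1

    def test_disjoint_strands_count_zero(self):
        ring = np.array(
            [[-10, -2], [10, -2], [10, -8], [-10, -8]],
            float,
        )
        assert cc.local_crossing_number(ring, (0.0, 0.0), 5.0) == 0

    def test_fig1d_slalom_signature(self, fig1d_result, fig1d):
        _, truth = fig1d
        counts = {"cross": [], "touch": []}
        for kind, x, y in truth.junctions:
            counts[kind].append(
                cc.local_crossing_number(fig1d_result.final_contour, (x, y), 5.0)
            )
        # the contour self-intersects twice per overlapping lobe: once at each
        # cross point of the pair; it only self-contacts at touch points
        assert counts["cross"] == [1, 1, 1, 1]
        assert counts["touch"] == [0, 0]
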