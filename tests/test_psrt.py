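"""Persistent Stanley-Reisner invariants against the brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cakl.oracle import (
    hochster_betti,
    persistent_graded_betti_bruteforce,
    vr_complex,
)
from cakl.psrt import (
    f_from_h,
    facet_count_curve,
    facet_persistent_number,
    graded_betti_j1,
    h_from_f,
    h_vector_at_scale,
    persistent_f_vector,
    persistent_graded_betti,
    persistent_h_vector,
)
from cakl.rips1d import complex_dimension, f_vector_at_scale, facet_barcode

point_clouds = st.sets(st.integers(0, 30), min_size=1, max_size=8).map(sorted)
scales = st.integers(0, 32)


class TestFacetPersistence:
    def test_worked_examples(self):
        bc = facet_barcode([1, 2, 10])
        assert facet_persistent_number(bc, 1, 1, 8) == 1
        assert facet_persistent_number(bc, 0, 0, 1) == 1  # only {10} survives past 1

    @settings(max_examples=40, derandomize=True)
    @given(points=point_clouds, t=scales)
    def test_diagonal_is_alive_census(self, points, t):
        bc = facet_barcode(points)
        for i in range(len(points)):
            alive = sum(1 for f in bc.alive(t) if f.dim == i)
            assert facet_persistent_number(bc, i, t, t) == alive

    def test_order_violation(self):
        bc = facet_barcode([1, 2])
        with pytest.raises(ValueError):
            facet_persistent_number(bc, 0, 3, 1)


class TestFacetCountCurve:
    def test_worked_example(self):
        F = facet_count_curve(facet_barcode([1, 2, 10]), [0, 1, 8, 9], dmax=3)
        assert F.tolist() == [[3, 1, 0, 0], [0, 1, 2, 0], [0, 0, 0, 1]]

    def test_single_point(self):
        F = facet_count_curve(facet_barcode([5]), [0, 1, 2], dmax=3)
        assert F[0].tolist() == [1, 1, 1] and not F[1:].any()

    def test_overflow_bucket(self):
        # 4 points in a tight cluster form a 3-simplex; with dmax=2 it lands in row 1
        F = facet_count_curve(facet_barcode([0, 1, 2, 3]), [3], dmax=2)
        assert F[:, 0].tolist() == [0, 1]


class TestGradedBetti:
    @pytest.mark.parametrize(
        "points,t,i,expected",
        [([1, 2, 10], 1, 1, 2), ([0, 10, 20], 5, 2, 2), ([1, 2, 10], 9, 1, 0)],
    )
    def test_worked_examples(self, points, t, i, expected):
        assert graded_betti_j1(points, t, i) == expected

    @settings(max_examples=100, derandomize=True)
    @given(points=point_clouds, t=scales, i=st.integers(1, 5))
    def test_matches_hochster_oracle(self, points, t, i):
        assert graded_betti_j1(points, t, i) == hochster_betti(vr_complex(points, t), i, 1)

    @settings(max_examples=25, derandomize=True)
    @given(points=st.sets(st.integers(0, 20), min_size=1, max_size=6).map(sorted), t=st.integers(0, 21))
    def test_higher_shifts_vanish_in_oracle(self, points, t):
        cx = vr_complex(points, t)
        for i in range(1, 3):
            for j in range(2, 4):
                assert hochster_betti(cx, i, j) == 0


class TestPersistentGradedBetti:
    @settings(max_examples=100, derandomize=True)
    @given(points=point_clouds, pair=st.tuples(scales, scales), i=st.integers(1, 4))
    def test_matches_unionfind_oracle(self, points, pair, i):
        t, t2 = min(pair), max(pair)
        assert persistent_graded_betti(points, t, t2, i, 1) == (
            persistent_graded_betti_bruteforce(points, t, t2, i)
        )

    @settings(max_examples=30, derandomize=True)
    @given(points=point_clouds, pair=st.tuples(scales, scales))
    def test_structural_zeros(self, points, pair):
        t, t2 = min(pair), max(pair)
        assert persistent_graded_betti(points, t, t2, 0, 0) == 1
        for i in range(1, 4):
            assert persistent_graded_betti(points, t, t2, i, 0) == 0
        assert persistent_graded_betti(points, t, t2, 0, 1) == 0
        for i in range(4):
            for j in range(2, 5):
                assert persistent_graded_betti(points, t, t2, i, j) == 0

    def test_worked_example(self):
        assert persistent_graded_betti([1, 2, 10], 1, 1, 1, 1) == 2


valid_f_vectors = st.integers(1, 6).flatmap(
    lambda d: st.lists(st.integers(0, 50), min_size=d, max_size=d).map(lambda v: [1] + v)
)


class TestTransforms:
    @pytest.mark.parametrize(
        "f,d,expected_h",
        [
            ([1, 3, 1], 2, [1, 1, -1]),
            ([1, 5], 1, [1, 4]),
            ([1, 3, 3, 1], 3, [1, 0, 0, 0]),
        ],
    )
    def test_h_from_f_examples(self, f, d, expected_h):
        assert h_from_f(f, d) == expected_h

    def test_f_from_h_examples(self):
        assert f_from_h([1, 1, -1], 2) == [1, 3, 1]
        # simplex h-vector inverts to the binomial pattern
        assert f_from_h([1, 0, 0, 0], 3) == [1, 3, 3, 1]

    def test_malformed_f_rejected(self):
        with pytest.raises(ValueError):
            h_from_f([2, 3], 1)

    @settings(max_examples=100, derandomize=True)
    @given(f=valid_f_vectors)
    def test_round_trip_identity(self, f):
        d = len(f) - 1
        assert f_from_h(h_from_f(f, d), d) == f


class TestPersistentVectors:
    @settings(max_examples=50, derandomize=True)
    @given(points=point_clouds, t=scales)
    def test_diagonal_reduces_to_classical(self, points, t):
        d = complex_dimension(points, t) + 1
        ph = persistent_h_vector(points, t, t)
        assert ph == h_vector_at_scale(points, t)
        assert persistent_f_vector(ph, d) == f_vector_at_scale(points, t)

    @settings(max_examples=40, derandomize=True)
    @given(points=point_clouds, pair=st.tuples(scales, scales))
    def test_h0_is_one_and_f_starts_at_one(self, points, pair):
        t, t2 = min(pair), max(pair)
        ph = persistent_h_vector(points, t, t2)
        assert ph[0] == 1
        d = complex_dimension(points, t2) + 1
        assert persistent_f_vector(ph, d)[0] == 1

    @settings(max_examples=30, derandomize=True)
    @given(points=point_clouds, t=scales)
    def test_full_simplex_h_is_unit_vector(self, points, t):
        t2 = max(points) - min(points)  # everything within one run
        t = min(t, t2)
        ph = persistent_h_vector(points, t, t2)
        assert ph == [1] + [0] * (len(points))
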