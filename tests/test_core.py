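"""CE-FDH ceiling estimation: worked examples, oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from conftest import ceiling_zone_grid, peers_bruteforce, random_sample
from ncarigor import (
    BivariateSample,
    DataError,
    DegenerateScopeError,
    cefdh_effect,
    find_peers,
)


def sample_of(points):
    arr = np.asarray(points, dtype=float)
    return BivariateSample(arr[:, 0], arr[:, 1])


class TestFindPeers:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 1), (1, 0)], [(0, 1)]),
            ([(1, 1), (2, 3), (3, 2), (4, 4)], [(1, 1), (2, 3), (4, 4)]),
            ([(2, 2)] * 5, [(2, 2)]),
            # same x: only the maximal y survives
            ([(1, 1), (1, 3), (2, 2)], [(1, 3)]),
        ],
    )
    def test_worked_examples(self, points, expected):
        peers = find_peers(sample_of(points))
        np.testing.assert_array_equal(peers, np.asarray(expected, dtype=float))

    def test_peers_strictly_increasing_in_x_and_y(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            peers = find_peers(random_sample(rng))
            assert np.all(np.diff(peers[:, 0]) > 0)
            assert np.all(np.diff(peers[:, 1]) > 0)

    def test_matches_pairwise_dominance_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            s = random_sample(rng)
            np.testing.assert_array_equal(find_peers(s), peers_bruteforce(s.x, s.y))


class TestCefdhEffect:
    @pytest.mark.parametrize(
        "points,c,s,d",
        [
            ([(0, 1), (1, 0)], 0.0, 1.0, 0.0),
            ([(0, 0), (1, 1)], 1.0, 1.0, 1.0),
            ([(1, 1), (2, 3), (3, 2), (4, 4)], 5.0, 9.0, 5.0 / 9.0),
        ],
    )
    def test_worked_examples(self, points, c, s, d):
        res = cefdh_effect(sample_of(points))
        assert res.ceiling_zone == pytest.approx(c)
        assert res.scope == pytest.approx(s)
        assert res.d == pytest.approx(d)

    def test_matches_grid_integration(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            s = random_sample(rng)
            res = cefdh_effect(s)
            tol = s.n * (s.x.max() - s.x.min()) / 20000 * (s.y.max() - s.y.min())
            assert abs(res.ceiling_zone - ceiling_zone_grid(s.x, s.y)) <= tol

    @pytest.mark.parametrize(
        "x,y,dim",
        [
            ([1, 1, 1], [1, 2, 3], "x"),
            ([1, 2, 3], [5, 5, 5], "y"),
            ([2, 2], [3, 3], "both x and y"),
        ],
    )
    def test_degenerate_scope_names_collapsed_dimension(self, x, y, dim):
        with pytest.raises(DegenerateScopeError) as err:
            cefdh_effect(BivariateSample(np.array(x, float), np.array(y, float)))
        assert err.value.dimension == dim

    @pytest.mark.parametrize(
        "x,y",
        [([1.0], [1.0]), ([1, 2], [1, np.nan]), ([1, np.inf], [0, 1]), ([1, 2, 3], [1, 2])],
    )
    def test_invalid_input_rejected(self, x, y):
        with pytest.raises(DataError):
            BivariateSample(np.asarray(x, float), np.asarray(y, float))


coords = st.floats(min_value=-1e3, max_value=1e3, allow_nan=False, width=64)


@st.composite
def scoped_samples(draw):
    n = draw(st.integers(min_value=2, max_value=30))
    x = np.array(draw(st.lists(coords, min_size=n, max_size=n)))
    y = np.array(draw(st.lists(coords, min_size=n, max_size=n)))
    assume(x.max() > x.min() and y.max() > y.min())
    return BivariateSample(x, y)


class TestEffectProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(scoped_samples())
    def test_effect_is_a_proportion(self, s):
        assert 0.0 <= cefdh_effect(s).d <= 1.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(scoped_samples())
    def test_occupied_corner_kills_effect(self, s):
        """An observation at (X_min, Y_max) leaves no empty upper-left space."""
        x = np.append(s.x, s.x.min())
        y = np.append(s.y, s.y.max())
        assert cefdh_effect(BivariateSample(x, y)).d == 0.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        scoped_samples(),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-100, max_value=100),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-100, max_value=100),
    )
    def test_affine_equivariance(self, s, a, b, c, e):
        """d is invariant under positive affine maps of either axis."""
        d0 = cefdh_effect(s).d
        d1 = cefdh_effect(BivariateSample(a * s.x + b, c * s.y + e)).d
        assert d1 == pytest.approx(d0, abs=1e-8)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(scoped_samples(), st.randoms(use_true_random=False))
    def test_dominated_point_is_inert(self, s, rnd):
        """A new point below/right of an existing one cannot move the ceiling."""
        d0 = cefdh_effect(s).d
        i = rnd.randrange(s.n)
        xi, yi = s.x[i], s.y[i]
        new_x = xi + rnd.random() * (s.x.max() - xi)
        new_y = s.y.min() + rnd.random() * (yi - s.y.min())
        grown = BivariateSample(np.append(s.x, new_x), np.append(s.y, new_y))
        assert cefdh_effect(grown).d == pytest.approx(d0, abs=1e-12)
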