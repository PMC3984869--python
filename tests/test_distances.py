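import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import dtw_brute
from ttclust.dataset import z_normalize
from ttclust.distances import (
    distance_to_similarity,
    dtw_distance,
    euclidean_distance,
    paa_transform,
    pairwise_matrix,
)

short_series = st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=5)


class TestEuclidean:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 0.0),
            ((0.0, 0.0), (3.0, 4.0), 5.0),
            ((1.0, 2.0, 3.0), (2.0, 2.0, 2.0), np.sqrt(2)),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert euclidean_distance(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_squared_flag(self):
        assert euclidean_distance(np.zeros(2), np.array([3.0, 4.0]), squared=True) == 25

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            euclidean_distance(np.zeros(3), np.zeros(4))

    def test_squared_preserves_ranking(self, rng):
        pairs = [(rng.normal(size=8), rng.normal(size=8)) for _ in range(20)]
        plain = [euclidean_distance(x, y) for x, y in pairs]
        squared = [euclidean_distance(x, y, squared=True) for x, y in pairs]
        assert np.array_equal(np.argsort(plain), np.argsort(squared))


class TestDtw:
    def test_self_distance_zero(self, rng):
        x = rng.normal(size=30)
        assert dtw_distance(x, x) == 0.0

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 6))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert dtw_distance(x, y) == pytest.approx(dtw_brute(x, y))

    @given(short_series, short_series)
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_nonnegativity(self, xs, ys):
        x, y = np.array(xs), np.array(ys)
        d = dtw_distance(x, y)
        assert d >= 0
        assert d == pytest.approx(dtw_distance(y, x))

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_diagonal_path(self, xs):
        rng = np.random.default_rng(len(xs))
        x = np.array(xs)
        y = x + rng.normal(size=x.size)
        assert dtw_distance(x, y) <= np.abs(x - y).sum() + 1e-9

    def test_warping_beats_euclidean_on_shifted_patterns(self):
        x = np.array([0.0, 5.0, 0.0, 0.0, 0.0])
        y = np.array([0.0, 0.0, 0.0, 5.0, 0.0])
        assert dtw_distance(x, y) < euclidean_distance(x, y)

    def test_path_normalized_known_value(self):
        # pure diagonal path of 2 lattice points, each with local cost 1
        assert dtw_distance(np.zeros(2), np.ones(2), normalize_by_path=True) == 1.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dtw_distance(np.array([]), np.ones(3))

    def test_infeasible_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            dtw_distance(np.zeros(6), np.zeros(2), window=1)

    def test_sakoe_chiba_band_never_below_unconstrained(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert dtw_distance(x, y, window=3) >= dtw_distance(x, y) - 1e-12


class TestPairwiseMatrix:
    def test_single_series(self):
        assert pairwise_matrix(np.ones((1, 4))).item() == 0.0

    def test_identical_series_all_zero(self):
        mat = pairwise_matrix(np.tile(np.arange(4.0), (3, 1)), metric="dtw")
        np.testing.assert_array_equal(mat, np.zeros((3, 3)))

    @pytest.mark.parametrize("metric", ["ed", "dtw"])
    def test_entries_match_elementwise_calls(self, metric, rng):
        data = rng.normal(size=(4, 6))
        mat = pairwise_matrix(data, metric=metric)
        fn = euclidean_distance if metric == "ed" else dtw_distance
        for i in range(4):
            for j in range(4):
                assert mat[i, j] == pytest.approx(fn(data[i], data[j]), abs=1e-9)
        np.testing.assert_allclose(mat, mat.T)
        assert (np.diag(mat) == 0).all()


class TestSimilarityConversion:
    def test_all_zero_distances_become_ones(self):
        np.testing.assert_array_equal(
            distance_to_similarity(np.zeros((3, 3)), method="minmax"), np.ones((3, 3))
        )

    def test_minmax_extremes(self, rng):
        d = np.abs(rng.normal(size=(4, 4)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        s = distance_to_similarity(d, method="minmax")
        assert s[np.unravel_index(np.argmax(d), d.shape)] == 0.0
        assert (np.diag(s) == 1).all()
        assert s.min() >= 0 and s.max() <= 1

    def test_pearson_equals_correlation_of_znormalized_series(self, rng):
        data = z_normalize(rng.normal(size=(6, 50)))
        d = pairwise_matrix(data, metric="ed")
        s = distance_to_similarity(d, method="pearson", length=50)
        expected = np.clip(np.corrcoef(data), 0, 1)
        np.testing.assert_allclose(s, expected, atol=1e-8)

    @pytest.mark.parametrize("method, kwargs", [("minmax", {}), ("inverse", {}),
                                                ("pearson", {"length": 8})])
    def test_reverses_distance_ordering(self, method, kwargs, rng):
        # correlated rows keep pearson similarities above the clip at 0,
        # where the ordering reversal is exact for every conversion
        base = rng.normal(size=8)
        data = base + 0.3 * rng.normal(size=(5, 8))
        d = pairwise_matrix(z_normalize(data), metric="ed")
        s = distance_to_similarity(d, method=method, **kwargs)
        iu = np.triu_indices(5, 1)
        if method == "pearson":
            assert (s[iu] > 0).all()
        order_d = np.argsort(d[iu])
        order_s = np.argsort(-s[iu])
        assert np.array_equal(order_d, order_s)

    def test_pearson_requires_length(self):
        with pytest.raises(ValueError, match="length"):
            distance_to_similarity(np.zeros((2, 2)), method="pearson")


class TestPaa:
    def test_ratio_one_is_identity(self, rng):
        x = rng.normal(size=10)
        np.testing.assert_array_equal(paa_transform(x, 1), x)

    def test_frame_means(self):
        np.testing.assert_array_equal(
            paa_transform(np.array([1.0, 1.0, 3.0, 3.0]), 2), [1.0, 3.0]
        )

    def test_length_128_ratio_6_matches_direct_averaging(self, rng):
        x = rng.normal(size=128)
        out = paa_transform(x, 6)
        assert out.shape == (22,)
        expected = [x[i : i + 6].mean() for i in range(0, 128, 6)]
        np.testing.assert_allclose(out, expected)

    def test_ratio_larger_than_length_rejected(self):
        with pytest.raises(ValueError):
            paa_transform(np.zeros(4), 5)
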