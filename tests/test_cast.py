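import numpy as np
import pytest

from ttclust.cast import (
    CastParams,
    SubCluster,
    affinity,
    alpha_for_target_subclusters,
    build_prototype,
    build_all_prototypes,
    cast_subcluster,
)
from ttclust.dataset import TimeSeriesDataset


def block_similarity(sizes, within=0.9, between=0.1):
    """Similarity matrix of perfectly separated blocks."""
    n = sum(sizes)
    sim = np.full((n, n), between)
    start = 0
    for s in sizes:
        sim[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(sim, 1.0)
    return sim


class TestAffinity:
    def test_all_identical_members(self):
        sim = np.ones((4, 4))
        assert affinity(0, [1, 2, 3], sim) == 1.0

    def test_singleton(self):
        sim = np.eye(2)
        sim[0, 1] = sim[1, 0] = 0.4
        assert affinity(0, [1], sim) == pytest.approx(0.4)

    def test_mean_of_three(self):
        sim = np.eye(4)
        sim[3, 0], sim[3, 1], sim[3, 2] = 0.9, 0.6, 0.3
        assert affinity(3, [0, 1, 2], sim) == pytest.approx(0.6)

    def test_empty_subcluster_rejected(self):
        with pytest.raises(ValueError):
            affinity(0, [], np.eye(2))


class TestCastSubcluster:
    def test_identity_similarity_gives_singletons(self):
        sub = cast_subcluster(np.eye(6), CastParams(alpha=0.5))
        assert sub.m == 6
        assert all(len(sc.member_ids) == 1 for sc in sub.subclusters)

    def test_all_ones_gives_single_subcluster(self):
        sub = cast_subcluster(np.ones((8, 8)), CastParams(alpha=0.9))
        assert sub.m == 1
        assert sorted(sub.subclusters[0].member_ids) == list(range(8))

    def test_two_separated_blobs_recovered(self):
        sim = block_similarity([3, 3])
        sub = cast_subcluster(sim, CastParams(alpha=0.7))
        assert sub.m == 2
        groups = {frozenset(sc.member_ids) for sc in sub.subclusters}
        assert groups == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_output_is_partition(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 25))
            raw = rng.uniform(size=(n, n))
            sim = (raw + raw.T) / 2
            np.fill_diagonal(sim, 1.0)
            alpha = float(rng.uniform(0.2, 0.9))
            sub = cast_subcluster(sim, CastParams(alpha=alpha))
            ids = sorted(x for sc in sub.subclusters for x in sc.member_ids)
            assert ids == list(range(n))

    def test_retained_affinity_meets_threshold_or_singleton(self, rng):
        raw = rng.uniform(size=(20, 20))
        sim = (raw + raw.T) / 2
        np.fill_diagonal(sim, 1.0)
        sub = cast_subcluster(sim, CastParams(alpha=0.6))
        for sc in sub.subclusters:
            if len(sc.member_ids) > 1:
                assert all(a >= 0.6 for a in sc.affinities.values())

    def test_subcluster_count_monotone_in_alpha(self, small_cbf):
        from ttclust.distances import distance_to_similarity, pairwise_matrix

        ds = small_cbf.z_normalized()
        sim = distance_to_similarity(
            pairwise_matrix(ds.values, "ed"), length=ds.length
        )
        counts = [
            cast_subcluster(sim, CastParams(alpha=a)).m
            for a in (0.3, 0.5, 0.7, 0.8, 0.9)
        ]
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]

    def test_alpha_extremes(self, rng):
        raw = rng.uniform(0, 0.8, size=(10, 10))
        sim = (raw + raw.T) / 2
        np.fill_diagonal(sim, 1.0)
        assert cast_subcluster(sim, CastParams(alpha=1 - 1e-9)).m == 10
        assert cast_subcluster(sim, CastParams(alpha=1e-9)).m == 1

    def test_deterministic(self, rng):
        raw = rng.uniform(size=(15, 15))
        sim = (raw + raw.T) / 2
        np.fill_diagonal(sim, 1.0)
        a = cast_subcluster(sim, CastParams(alpha=0.55))
        b = cast_subcluster(sim, CastParams(alpha=0.55))
        assert [sc.member_ids for sc in a.subclusters] == [
            sc.member_ids for sc in b.subclusters
        ]


class TestPrototype:
    def test_identical_members_reproduce_the_series(self):
        data = TimeSeriesDataset(np.tile([1.0, 2.0, 3.0], (3, 1)))
        sc = SubCluster([0, 1, 2], {0: 1.0, 1: 1.0, 2: 1.0})
        np.testing.assert_allclose(build_prototype(sc, data), [1.0, 2.0, 3.0])

    def test_literal_weighted_combination(self):
        data = TimeSeriesDataset(np.array([[0.0, 0.0], [2.0, 2.0]]))
        sc = SubCluster([0, 1], {0: 1.0, 1: 0.5})
        np.testing.assert_allclose(build_prototype(sc, data), [0.5, 0.5])

    def test_uniform_affinity_scales_the_mean(self, rng):
        vals = rng.normal(size=(4, 6))
        data = TimeSeriesDataset(vals)
        a = 0.7
        sc = SubCluster([0, 1, 2, 3], {i: a for i in range(4)})
        np.testing.assert_allclose(
            build_prototype(sc, data), a * vals.mean(axis=0), atol=1e-12
        )

    def test_affinity_normalization_is_weighted_mean(self):
        data = TimeSeriesDataset(np.array([[0.0, 0.0], [2.0, 2.0]]))
        sc = SubCluster([0, 1], {0: 1.0, 1: 0.5})
        np.testing.assert_allclose(
            build_prototype(sc, data, normalize="affinity"), [2 / 3, 2 / 3]
        )

    def test_missing_affinity_rejected(self):
        data = TimeSeriesDataset(np.zeros((2, 3)))
        sc = SubCluster([0, 1], {0: 1.0})
        with pytest.raises(ValueError, match="missing affinity"):
            build_prototype(sc, data)


class TestTargetSubclusters:
    def test_hits_exact_count_on_blocks(self, easy_blocks):
        from ttclust.distances import distance_to_similarity, pairwise_matrix

        ds = easy_blocks.z_normalized()
        sim = distance_to_similarity(
            pairwise_matrix(ds.values, "ed"), length=ds.length
        )
        alpha, sub = alpha_for_target_subclusters(sim, 3)
        assert sub.m == 3
        assert 0 < alpha < 1
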