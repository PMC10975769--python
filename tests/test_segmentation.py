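from itertools import product

import numpy as np
import pytest

from rkmd.cloud import PointCloud
from rkmd.segmentation import (
    ElbowCurve,
    dice_similarity,
    kmeans,
    match_clusters,
    segment_leaves,
    segmentation_threshold,
    select_k_elbow,
    wcss_curve,
)


def _blobs(rng, centers, n_per=30, sd=0.1):
    pts = np.vstack([rng.normal(c, sd, size=(n_per, 3)) for c in centers])
    return PointCloud(pts)


def _wcss_of(pts, labels, k):
    total = 0.0
    for c in range(k):
        members = pts[labels == c]
        if len(members):
            total += ((members - members.mean(axis=0)) ** 2).sum()
    return total


class TestKmeans:
    def test_k1_closed_form(self, rng):
        pts = rng.normal(size=(40, 3))
        res = kmeans(PointCloud(pts), 1, seed=0)
        assert np.allclose(res.centroids[0], pts.mean(axis=0))
        assert res.wcss == pytest.approx(((pts - pts.mean(axis=0)) ** 2).sum())

    def test_two_points_two_clusters(self):
        res = kmeans(PointCloud([[0, 0, 0], [5, 5, 5]]), 2, seed=1)
        assert res.wcss == pytest.approx(0.0, abs=1e-12)
        assert set(res.labels.tolist()) == {0, 1}

    def test_separated_blobs_recovered_exactly(self, rng):
        centers = [(0, 0, 0), (50, 0, 0), (0, 50, 0)]
        cloud = _blobs(rng, centers)
        res = kmeans(cloud, 3, seed=2)
        truth = np.repeat([0, 1, 2], 30)
        # exact recovery up to label permutation
        for c in range(3):
            assert len(np.unique(truth[res.labels == c])) == 1

    def test_centroids_are_cluster_means(self, rng):
        cloud = PointCloud(rng.normal(size=(60, 3)))
        res = kmeans(cloud, 4, seed=3)
        for c in range(4):
            members = cloud.points[res.labels == c]
            assert len(members) > 0  # no empty clusters survive
            assert np.allclose(res.centroids[c], members.mean(axis=0), atol=1e-6)

    def test_brute_force_optimal_on_tiny_instances(self, rng):
        """Exhaustively enumerated partitions bound the WCSS; restarted
        Lloyd attains the global optimum on <= 12-point instances."""
        pts = rng.normal(size=(8, 3)) * 3
        for k in (2, 3):
            best = np.inf
            for assign in product(range(k), repeat=8):
                labels = np.asarray(assign)
                if len(set(assign)) < k:
                    continue
                best = min(best, _wcss_of(pts, labels, k))
            res = kmeans(PointCloud(pts), k, seed=4, n_init=64)
            assert res.wcss == pytest.approx(best, rel=1e-9)

    def test_matches_sklearn_consensus(self, rng):
        sklearn = pytest.importorskip("sklearn.cluster")
        pts = rng.normal(size=(200, 3)) * [5, 2, 1]
        ours = kmeans(PointCloud(pts), 4, seed=5, n_init=20)
        ref = sklearn.KMeans(n_clusters=4, n_init=20, random_state=0).fit(pts)
        assert ours.wcss == pytest.approx(ref.inertia_, rel=0.01)

    def test_invalid_k(self, rng):
        with pytest.raises(ValueError):
            kmeans(PointCloud(rng.normal(size=(5, 3))), 6, seed=0)


class TestElbow:
    def test_wcss_curve_nonincreasing(self, rng):
        cloud = _blobs(rng, [(0, 0, 0), (10, 0, 0), (0, 10, 0)])
        curve = wcss_curve(cloud, 1, 6, seed=1)
        assert all(b <= a * 1.01 for a, b in zip(curve.wcss, curve.wcss[1:]))

    def test_single_k_total_variance(self, rng):
        pts = rng.normal(size=(30, 3))
        curve = wcss_curve(PointCloud(pts), 1, 1, seed=0)
        assert curve.wcss[0] == pytest.approx(((pts - pts.mean(axis=0)) ** 2).sum())

    def test_identical_points_zero_wcss(self):
        cloud = PointCloud(np.tile([1.0, 2.0, 3.0], (20, 1)))
        curve = wcss_curve(cloud, 1, 4, seed=0)
        assert np.allclose(curve.wcss, 0.0)

    def test_knee_by_hand(self):
        # second differences of [100, 20, 18, 17]: at k=2: 100-40+18=78; k=3: 1
        curve = ElbowCurve([1, 2, 3, 4], [100.0, 20.0, 18.0, 17.0])
        assert select_k_elbow(curve) == 2

    def test_linear_decay_ties_to_first_interior(self):
        curve = ElbowCurve([1, 2, 3, 4, 5], [50.0, 40.0, 30.0, 20.0, 10.0])
        assert select_k_elbow(curve) == 2

    def test_three_blob_knee(self, rng):
        cloud = _blobs(rng, [(0, 0, 0), (40, 0, 0), (0, 40, 0)], n_per=50, sd=0.5)
        curve = wcss_curve(cloud, 1, 6, seed=2)
        assert select_k_elbow(curve) == 3

    def test_too_short_curve_raises(self):
        with pytest.raises(ValueError):
            select_k_elbow(ElbowCurve([1, 2], [10.0, 5.0]))

    def test_k_max_exceeding_points_raises(self, rng):
        with pytest.raises(ValueError):
            wcss_curve(PointCloud(rng.normal(size=(4, 3))), 1, 10, seed=0)


class TestDice:
    def test_identity(self):
        assert dice_similarity([1, 2, 3], [1, 2, 3]) == 1.0

    def test_disjoint(self):
        assert dice_similarity([1, 2], [3, 4]) == 0.0

    def test_worked_example(self):
        detected = np.arange(80)
        reference = np.arange(20, 140)  # overlap 60, sizes 80 and 120
        assert dice_similarity(detected, reference) == pytest.approx(0.6)

    def test_symmetric_and_bounded(self, rng):
        a = rng.choice(100, size=30, replace=False)
        b = rng.choice(100, size=50, replace=False)
        d1, d2 = dice_similarity(a, b), dice_similarity(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0

    def test_both_empty_raises(self):
        with pytest.raises(ValueError):
            dice_similarity([], [])


@pytest.mark.parametrize(
    "n,expected", [(0, 0.88), (5, 0.88), (10, 0.88), (11, 0.84), (20, 0.84),
                   (25, 0.84), (26, 0.80), (30, 0.80)]
)
def test_dice_threshold_schedule(n, expected):
    assert segmentation_threshold(n) == expected


def test_dice_threshold_negative_raises():
    with pytest.raises(ValueError):
        segmentation_threshold(-1)


class TestSegmentLeaves:
    def test_three_blob_plant_with_reference(self, rng):
        centers = [(0, 0, 0), (60, 0, 0), (0, 60, 0)]
        cloud = _blobs(rng, centers, n_per=60, sd=1.0)
        labels = np.repeat([f"leaf_{i}" for i in (1, 2, 3)], 60)
        result, gates = segment_leaves(cloud, seed=1, k_min=1, k_max=8,
                                       reference_labels=labels)
        assert result.k == 3
        assert all(g.similarity >= 0.88 for g in gates)

    def test_empty_cloud_raises(self):
        with pytest.raises(ValueError):
            segment_leaves(PointCloud(np.zeros((0, 3))), seed=0)

    def test_greedy_matching_unique_clusters(self, rng):
        cloud = _blobs(rng, [(0, 0, 0), (30, 0, 0)], n_per=40)
        labels = np.repeat(["leaf_1", "leaf_2"], 40)
        result = kmeans(cloud, 2, seed=0)
        gates = match_clusters(result, labels)
        used = [g.cluster for g in gates if g.cluster is not None]
        assert len(used) == len(set(used))
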