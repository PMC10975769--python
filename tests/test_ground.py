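from itertools import combinations

import numpy as np
import pytest

from rkmd.cloud import PointCloud
from rkmd.ground import (
    ColorRule,
    NoPlaneFoundError,
    Plane,
    RansacConfig,
    color_ground_filter,
    expected_stem_count,
    point_plane_distance,
    ransac_plane,
    remove_ground,
    threshold_sweep,
)
from rkmd.synthetic import generate_scene


class TestPlane:
    def test_normalizes_coefficients(self):
        p = Plane(0, 0, 2, 4)
        assert p.c == pytest.approx(1.0)
        assert p.d == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "point,plane,expected",
        [
            ((0, 0, 1), Plane(0, 0, 1, 0), 1.0),
            ((3, -2, 0), Plane(0, 0, 1, 0), 0.0),
            ((1, 2, 3), Plane(1, 1, 1, 0), 6.0 / np.sqrt(3)),  # |1+2+3|/sqrt(3)
        ],
    )
    def test_point_plane_distance(self, point, plane, expected):
        assert point_plane_distance(point, plane) == pytest.approx(expected)


def _brute_force_best_inliers(pts: np.ndarray, dtr: float) -> int:
    best = 0
    for i, j, k in combinations(range(len(pts)), 3):
        n = np.cross(pts[j] - pts[i], pts[k] - pts[i])
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            continue
        n = n / norm
        d = np.abs((pts - pts[i]) @ n)
        best = max(best, int((d < dtr).sum()))
    return best


class TestRansacPlane:
    def test_perfect_plane_all_inliers(self, rng):
        pts = np.column_stack([rng.uniform(size=(100, 2)) * 10, np.zeros(100)])
        plane, mask = ransac_plane(PointCloud(pts), RansacConfig(seed=1))
        assert mask.sum() == 100
        assert abs(plane.c) == pytest.approx(1.0, abs=1e-9)

    def test_matches_exhaustive_enumeration(self, rng):
        """With a saturated iteration budget the sampled search attains the
        same consensus as brute force over all C(n,3) planes."""
        pts = np.vstack(
            [
                np.column_stack([rng.uniform(size=(30, 2)) * 10, rng.normal(0, 0.02, 30)]),
                rng.uniform(5, 15, size=(10, 3)) + [0, 0, 10],
            ]
        )
        cfg = RansacConfig(distance_threshold=0.1, max_iterations=20000, seed=3,
                           early_exit_fraction=1.1)
        _, mask = ransac_plane(PointCloud(pts), cfg, refit=False)
        assert mask.sum() == _brute_force_best_inliers(pts, 0.1)

    def test_outlier_contaminated_plane(self, rng):
        pts = np.vstack(
            [
                np.column_stack([rng.uniform(size=(95, 2)) * 20, np.zeros(95)]),
                np.column_stack([rng.uniform(size=(5, 2)) * 20, rng.uniform(10, 20, 5)]),
            ]
        )
        _, mask = ransac_plane(PointCloud(pts), RansacConfig(distance_threshold=0.1, seed=2))
        assert mask.sum() == 95

    def test_collinear_raises(self):
        pts = np.outer(np.arange(3.0), [1.0, 0.0, 0.0])
        with pytest.raises(NoPlaneFoundError):
            ransac_plane(PointCloud(pts), RansacConfig(seed=0, max_iterations=50))

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            ransac_plane(PointCloud([[0, 0, 0], [1, 1, 1]]), RansacConfig())

    def test_inliers_monotone_in_threshold(self, rng):
        """Same seed, same data: the consensus never shrinks as the
        distance threshold grows (full budget, no refit)."""
        pts = rng.normal(size=(60, 3)) * [10, 10, 1]
        counts = [
            ransac_plane(
                PointCloud(pts),
                RansacConfig(distance_threshold=dt, seed=5, max_iterations=300,
                             early_exit_fraction=1.1),
                refit=False,
            )[1].sum()
            for dt in (0.2, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(50, 3))
        cfg = RansacConfig(seed=9)
        p1, m1 = ransac_plane(PointCloud(pts), cfg)
        p2, m2 = ransac_plane(PointCloud(pts), cfg)
        assert np.array_equal(m1, m2)
        assert (p1.a, p1.b, p1.c, p1.d) == (p2.a, p2.b, p2.c, p2.d)


class TestColorFilter:
    def test_all_green_cloud_no_candidates(self):
        cloud = PointCloud(np.zeros((5, 3)), colors=np.tile([0.2, 0.8, 0.2], (5, 1)))
        cand, rest = color_ground_filter(cloud)
        assert len(cand) == 0 and len(rest) == 5

    def test_scene_labels_recovered_exactly(self, three_leaf_scene_spec):
        cloud, labels, _ = generate_scene(three_leaf_scene_spec)
        cand, rest = color_ground_filter(cloud)
        assert set(np.unique(labels[cand])) == {"ground"}
        assert "ground" not in labels[rest]

    def test_empty_cloud(self):
        cloud = PointCloud(np.zeros((0, 3)), colors=np.zeros((0, 3)))
        cand, rest = color_ground_filter(cloud)
        assert len(cand) == 0 and len(rest) == 0

    def test_missing_colors_raises(self):
        with pytest.raises(ValueError, match="colors"):
            color_ground_filter(PointCloud(np.zeros((3, 3))))


class TestRemoveGround:
    def test_noise_free_scene_perfect_confusion(self, three_leaf_scene_spec):
        import dataclasses

        spec = dataclasses.replace(three_leaf_scene_spec, ground_noise_sigma=0.0)
        spec.leaves = [dataclasses.replace(lf, noise_sigma=0.0) for lf in spec.leaves]
        cloud, labels, _ = generate_scene(spec)
        plant, ground, report = remove_ground(cloud, RansacConfig(seed=2))
        is_ground = labels == "ground"
        assert (report.ground_mask & is_ground).sum() == is_ground.sum()
        leaf_mask = np.char.startswith(labels.astype(str), "leaf")
        assert (report.ground_mask & leaf_mask).sum() == 0

    def test_partition_conservation(self, three_leaf_scene_spec):
        cloud, _, _ = generate_scene(three_leaf_scene_spec)
        plant, ground, _ = remove_ground(cloud, RansacConfig(seed=4))
        assert len(plant) + len(ground) == len(cloud)

    def test_no_ground_colored_points_vacuous(self):
        cloud = PointCloud(
            np.random.default_rng(0).normal(size=(20, 3)),
            colors=np.tile([0.2, 0.8, 0.2], (20, 1)),
        )
        plant, ground, report = remove_ground(cloud, RansacConfig(seed=0))
        assert len(plant) == 20 and len(ground) == 0
        assert report.plane is None


class TestExpectedStemCount:
    @pytest.mark.parametrize(
        "r,h,rho,expected",
        [(1, 1, 1, np.pi), (0, 5, 5, 0.0), (2, 3, 10, 120 * np.pi)],
    )
    def test_values(self, r, h, rho, expected):
        assert expected_stem_count(r, h, rho) == pytest.approx(expected)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            expected_stem_count(-1, 1, 1)


def test_threshold_sweep_reports_nondecreasing_consensus(rng):
    pts = rng.normal(size=(80, 3)) * [10, 10, 0.5]
    sweep = threshold_sweep(PointCloud(pts), [0.2, 0.5, 1.0, 2.0], seed=1)
    counts = [c for _, c in sweep]
    assert counts == sorted(counts)
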