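import numpy as np
import pytest
from scipy.spatial import ConvexHull

from rkmd.cloud import DegenerateGeometryError, PointCloud, TriangleMesh
from rkmd.measure import (
    BoundaryExtractionError,
    MeasureConfig,
    extract_boundary,
    identify_base_tip,
    leaf_area,
    leaf_length,
    leaf_perimeter,
    measure_leaf,
    triangle_area,
)
from rkmd.synthetic import LeafSpec, generate_leaf


def _rot_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


class TestIdentifyBaseTip:
    def test_flat_leaf_extremes(self, flat_leaf_small):
        cloud, _ = flat_leaf_small
        base, tip = identify_base_tip(cloud)
        xs = cloud.points[:, 0]
        assert {xs[base], xs[tip]} == {xs.min(), xs.max()}

    def test_rotation_recovers_same_points(self, flat_leaf_small):
        cloud, _ = flat_leaf_small
        base0, tip0 = identify_base_tip(cloud)
        rot = cloud.transformed(_rot_z(np.pi / 2), [0, 0, 0])
        base1, tip1 = identify_base_tip(rot)
        assert {base0, tip0} == {base1, tip1}

    def test_stem_reference_selects_base(self, flat_leaf_small):
        cloud, _ = flat_leaf_small
        far_x = cloud.points[:, 0].max()
        base, tip = identify_base_tip(cloud, stem_reference=[far_x + 1, 0, 0])
        assert cloud.points[base, 0] == cloud.points[:, 0].max()

    def test_coincident_points_raise(self):
        cloud = PointCloud(np.tile([1.0, 2.0, 3.0], (5, 1)))
        with pytest.raises(DegenerateGeometryError):
            identify_base_tip(cloud)


class TestLeafLength:
    def test_flat_leaf_is_chord_for_any_n1(self, flat_leaf_small):
        """On a flat leaf the lifted heights are all zero, so the polyline
        collapses to the base-tip chord regardless of n1."""
        cloud, truth = flat_leaf_small
        chord = leaf_length(cloud, MeasureConfig(n1=1))
        for n1 in (13, 50, 200):
            assert leaf_length(cloud, MeasureConfig(n1=n1)) == pytest.approx(
                chord, rel=1e-9
            )
        # the sampled cloud stops just short of the analytic tips
        assert chord == pytest.approx(truth.length, rel=0.02)

    def test_half_cylinder_arc(self):
        # 180-degree bend of radius 20: true length pi * 20 vs chord 40;
        # for this extreme bend the fixed horizontal plane is the right
        # measurement plane (the PCA plane is ambiguous at 180 degrees)
        spec = LeafSpec(semi_major=np.pi * 10, semi_minor=10, bend_radius=20,
                        bend_angle=180, density=12.0, noise_sigma=0.0)
        cloud, truth = generate_leaf(spec, seed=3)
        assert truth.length == pytest.approx(np.pi * 20)
        lp = leaf_length(cloud, MeasureConfig(n1=50, plane="xy"))
        assert lp == pytest.approx(np.pi * 20, rel=0.02)
        assert lp > 45.0  # far beyond the chord

    def test_single_segment_gives_chord(self):
        spec = LeafSpec(semi_major=np.pi * 10, semi_minor=10, bend_radius=20,
                        bend_angle=180, density=12.0, noise_sigma=0.0)
        cloud, _ = generate_leaf(spec, seed=3)
        chordish = leaf_length(cloud, MeasureConfig(n1=1, plane="xy",
                                                    tip_landmark_points=1))
        assert chordish == pytest.approx(40.0, rel=0.01)

    def test_non_decreasing_in_n1_and_converges(self):
        spec = LeafSpec(semi_major=20, semi_minor=10, bend_radius=30, bend_angle=70,
                        density=25.0, noise_sigma=0.0)
        cloud, truth = generate_leaf(spec, seed=4)
        values = [
            leaf_length(cloud, MeasureConfig(n1=n1, plane="xy"))
            for n1 in (1, 4, 16, 64)
        ]
        assert all(a <= b * 1.001 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(truth.length, rel=0.01)


class TestBoundary:
    def test_square_corners(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], float)
        boundary, _ = extract_boundary(PointCloud(pts), MeasureConfig(boundary_alpha=20.0))
        assert len(boundary) == 4
        assert leaf_perimeter(boundary) == pytest.approx(40.0)

    def test_convex_disc_matches_hull(self, rng):
        r = np.sqrt(rng.uniform(size=600)) * 10
        t = rng.uniform(0, 2 * np.pi, 600)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(600)])
        cloud = PointCloud(pts)
        boundary, idx = extract_boundary(cloud, MeasureConfig(boundary_alpha=1e6))
        hull = ConvexHull(pts[:, :2])
        assert set(idx.tolist()) == set(hull.vertices.tolist())

    def test_crescent_keeps_concave_points(self, rng):
        t = rng.uniform(0, np.pi, 800)
        r = rng.uniform(8, 10, 800)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(800)])
        cloud = PointCloud(pts)
        boundary, idx = extract_boundary(cloud, MeasureConfig(boundary_alpha=2.0))
        hull = set(ConvexHull(pts[:, :2]).vertices.tolist())
        assert len(set(idx.tolist()) - hull) > 0  # concave arc members

    def test_clockwise_winding(self, flat_leaf_small):
        cloud, _ = flat_leaf_small
        boundary, _ = extract_boundary(cloud)
        from rkmd.measure import _project

        uv, _, _ = _project(cloud, "pca")
        # recompute signed area of the boundary polygon in the same frame
        bl, _ = extract_boundary(cloud)
        poly = (bl - cloud.points.mean(axis=0)) @ _project(cloud, "pca")[2].T
        x, y = poly[:, 0], poly[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed <= 0

    def test_tiny_alpha_fails_cleanly(self, flat_leaf_small):
        cloud, _ = flat_leaf_small
        with pytest.raises(BoundaryExtractionError):
            extract_boundary(cloud, MeasureConfig(boundary_alpha=1e-3))


class TestPerimeter:
    def test_square(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], float)
        assert leaf_perimeter(pts) == pytest.approx(40.0)

    def test_inscribed_polygon_circle(self):
        t = np.linspace(0, 2 * np.pi, 361)[:-1]
        pts = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros(360)])
        exact = 2 * 360 * 10 * np.sin(np.pi / 360)
        assert leaf_perimeter(pts) == pytest.approx(exact, rel=1e-4)

    def test_right_triangle(self):
        pts = np.array([[0, 0, 0], [3, 0, 0], [3, 4, 0]], float)
        assert leaf_perimeter(pts) == pytest.approx(12.0)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            leaf_perimeter(np.zeros((2, 3)))


class TestTriangleAndMeshArea:
    @pytest.mark.parametrize(
        "v1,v2,v3,expected",
        [
            ((0, 0, 0), (1, 0, 0), (0, 1, 0), 0.5),
            ((0, 0, 0), (1, 1, 1), (2, 2, 2), 0.0),
            ((0, 0, 0), (2, 0, 0), (0, 0, 3), 3.0),
        ],
    )
    def test_triangle_area(self, v1, v2, v3, expected):
        assert triangle_area(v1, v2, v3) == pytest.approx(expected)

    def test_leaf_area_single_face(self):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        assert leaf_area(mesh) == pytest.approx(0.5)

    def test_unit_square_two_triangles(self):
        mesh = TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], [[0, 1, 2], [1, 3, 2]]
        )
        assert leaf_area(mesh) == pytest.approx(1.0)

    def test_area_scale_applied(self):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        assert leaf_area(mesh, area_scale=2.0) == pytest.approx(1.0)

    def test_empty_mesh_raises(self):
        with pytest.raises(ValueError):
            leaf_area(TriangleMesh(np.zeros((3, 3)), np.zeros((0, 3), dtype=int)))


class TestMeasureLeaf:
    def test_flat_ellipse_all_three(self, flat_leaf_small):
        # length tolerance reflects the sampled cloud stopping short of the
        # analytic tips at this density (finer clouds get within 1%)
        cloud, truth = flat_leaf_small
        m = measure_leaf(cloud)
        assert m.length == pytest.approx(truth.length, rel=0.02)
        assert m.perimeter == pytest.approx(truth.perimeter, rel=0.02)
        assert m.area == pytest.approx(truth.area, rel=0.03)
        assert m.length <= m.perimeter

    def test_rigid_motion_invariance(self, flat_leaf_small):
        """Rotation + translation change each measurement only at the
        discretization level (identical topology is not guaranteed under
        floating-point rotation, so agreement is asserted to 0.5%)."""
        cloud, _ = flat_leaf_small
        m0 = measure_leaf(cloud)
        moved = cloud.transformed(_rot_z(1.1), [50.0, -20.0, 7.0])
        m1 = measure_leaf(moved)
        assert m1.length == pytest.approx(m0.length, rel=5e-3)
        assert m1.perimeter == pytest.approx(m0.perimeter, rel=5e-3)
        assert m1.area == pytest.approx(m0.area, rel=5e-3)

    def test_two_point_cloud_errors(self):
        with pytest.raises((ValueError, DegenerateGeometryError)):
            measure_leaf(PointCloud([[0, 0, 0], [1, 0, 0]]))

    def test_scales_applied(self, flat_leaf_small):
        cloud, _ = flat_leaf_small
        base = measure_leaf(cloud)
        scaled = measure_leaf(cloud, MeasureConfig(length_scale=2.0, area_scale=3.0))
        assert scaled.length == pytest.approx(2 * base.length, rel=1e-9)
        assert scaled.perimeter == pytest.approx(2 * base.perimeter, rel=1e-9)
        assert scaled.area == pytest.approx(3 * base.area, rel=1e-9)
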