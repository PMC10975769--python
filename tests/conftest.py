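import numpy as np
import pytest

from rkmd.cloud import PointCloud
from rkmd.synthetic import LeafSpec, SceneSpec, generate_leaf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_leaf_small():
    """Noise-free flat elliptical leaf, small enough for fast tests."""
    spec = LeafSpec(semi_major=15.0, semi_minor=8.0, noise_sigma=0.0, density=8.0)
    return generate_leaf(spec, seed=7)


def make_three_leaf_scene_spec() -> SceneSpec:
    """Well-separated three-leaf plant over a ground patch (fast sizes)."""
    leaves = []
    for i, yaw in enumerate((0.0, 120.0, 240.0)):
        rad = np.radians(yaw)
        leaves.append(
            LeafSpec(
                semi_major=16.0,
                semi_minor=8.0,
                bend_radius=60.0,
                bend_angle=float(np.degrees(32.0 / 60.0)),
                attach_point=(12.0 * np.cos(rad), 12.0 * np.sin(rad), 18.0 + 4.0 * i),
                yaw=yaw,
                pitch=-25.0,
                density=8.0,
            )
        )
    return SceneSpec(
        leaves=leaves,
        stem_radius=2.0,
        stem_height=26.0,
        stem_density=4.0,
        ground_extent=80.0,
        ground_density=1.5,
        seed=99,
    )


@pytest.fixture
def three_leaf_scene_spec():
    return make_three_leaf_scene_spec()


def grid_cloud(n: int = 25, spacing: float = 1.0, z: float = 0.0, jitter: float = 0.0,
               seed: int = 0) -> PointCloud:
    """n x n planar grid with +z normals.  A small in-plane ``jitter``
    breaks the exact cocircularity of lattice cells (four corners on one
    circle), which is degenerate for ball pivoting."""
    xs = np.arange(n) * spacing
    xx, yy = np.meshgrid(xs, xs)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, z)])
    if jitter:
        pts[:, :2] += np.random.default_rng(seed).uniform(-jitter, jitter, (n * n, 2))
    normals = np.tile([0.0, 0.0, 1.0], (n * n, 1))
    return PointCloud(pts, normals=normals)


def smoothness_ring(angle_between: float, m: int = 40, radius: float = 100.0) -> PointCloud:
    """Ring of m points whose normals alternate between two directions
    ``angle_between`` degrees apart: every point's 20 nearest neighbors are
    10 of each class, so the mean neighbor-normal angle is exactly half of
    ``angle_between``."""
    theta = 2.0 * np.pi * np.arange(m) / m
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(m)])
    a = np.radians(angle_between)
    n0 = np.array([0.0, 0.0, 1.0])
    n1 = np.array([np.sin(a), 0.0, np.cos(a)])
    normals = np.where((np.arange(m) % 2 == 0)[:, None], n0, n1)
    return PointCloud(pts, normals=normals)
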