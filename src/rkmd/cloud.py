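"""Core point-cloud containers and geometric primitives.

All coordinates are millimetres end to end; colors are per-point RGB
normalized to [0, 1]; normals are unit 3-vectors.  These types are the
currency passed between every pipeline stage (ground removal, segmentation,
smoothing, measurement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


class DegenerateGeometryError(ValueError):
    """Raised when a geometric fit is requested on degenerate input."""


@dataclass
class PointCloud:
    """N points in mm with optional per-point colors and normals.

    Parameters
    ----------
    points : (N, 3) float array
        Cartesian coordinates in millimetres.  Must be finite.
    colors : (N, 3) float array, optional
        RGB per point, each channel in [0, 1].
    normals : (N, 3) float array, optional
        Unit normals (Euclidean norm 1 within 1e-6).
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        n = len(self.points)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)
            if len(self.colors) != n:
                raise ValueError(f"colors count {len(self.colors)} != point count {n}")
            if n and (self.colors.min() < -1e-12 or self.colors.max() > 1 + 1e-12):
                raise ValueError("color channels must lie in [0, 1]")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
            if len(self.normals) != n:
                raise ValueError(f"normals count {len(self.normals)} != point count {n}")
            if n:
                norms = np.linalg.norm(self.normals, axis=1)
                if np.abs(norms - 1.0).max() > 1e-6:
                    raise ValueError("normals must be unit vectors (within 1e-6)")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index) -> "PointCloud":
        """Sub-cloud at the given indices / boolean mask, attributes carried along."""
        return PointCloud(
            self.points[index],
            None if self.colors is None else self.colors[index],
            None if self.normals is None else self.normals[index],
        )

    def transformed(self, rotation: np.ndarray, translation) -> "PointCloud":
        """Rigidly moved copy: ``p -> R p + t`` (normals rotated, colors kept)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return PointCloud(
            self.points @ R.T + t,
            None if self.colors is None else self.colors.copy(),
            None if self.normals is None else self.normals @ R.T,
        )


@dataclass(frozen=True)
class AxisAlignedBox:
    """Axis-aligned bounding box given by two opposite corners (mm)."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "min_corner", np.asarray(self.min_corner, float).reshape(3))
        object.__setattr__(self, "max_corner", np.asarray(self.max_corner, float).reshape(3))
        if np.any(self.min_corner > self.max_corner):
            raise ValueError("min_corner must be <= max_corner componentwise")

    def contains(self, points: np.ndarray, pad: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the closed box, optionally padded by ``pad`` mm."""
        p = np.atleast_2d(np.asarray(points, float))
        return np.all((p >= self.min_corner - pad) & (p <= self.max_corner + pad), axis=1)

    @property
    def extent(self) -> np.ndarray:
        return self.max_corner - self.min_corner


@dataclass(frozen=True)
class OrientedBox:
    """PCA-aligned bounding box: center, orthonormal axes, half extents (mm)."""

    center: np.ndarray
    axes: np.ndarray  # (3, 3), rows are unit axes
    half_extents: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        object.__setattr__(self, "axes", np.asarray(self.axes, float).reshape(3, 3))
        object.__setattr__(self, "half_extents", np.asarray(self.half_extents, float).reshape(3))
        gram = self.axes @ self.axes.T
        if np.abs(gram - np.eye(3)).max() > 1e-6:
            raise ValueError("axes must be orthonormal within 1e-6")
        if np.any(self.half_extents < -1e-12):
            raise ValueError("half extents must be nonnegative")

    @property
    def volume(self) -> float:
        return float(8.0 * np.prod(self.half_extents))


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle mesh: vertices in mm and (M, 3) face index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", np.asarray(self.vertices, float).reshape(-1, 3))
        faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        object.__setattr__(self, "faces", faces)
        if len(faces):
            if faces.min() < 0 or faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")
            if np.any(
                (faces[:, 0] == faces[:, 1])
                | (faces[:, 1] == faces[:, 2])
                | (faces[:, 0] == faces[:, 2])
            ):
                raise ValueError("faces must not repeat a vertex index")

    def __len__(self) -> int:
        return len(self.faces)


def uniform_downsample(cloud: PointCloud, every_k: int) -> PointCloud:
    """Keep every ``every_k``-th point (indices 0, k, 2k, ...), order preserved.

    Output size is ``ceil(N / every_k)``.
    """
    if every_k < 1:
        raise ValueError(f"every_k must be >= 1, got {every_k}")
    return cloud.select(slice(None, None, int(every_k)))


def radius_downsample(cloud: PointCloud, radius: float) -> PointCloud:
    """Greedy blue-noise style downsampling: keep a point unless an
    already-kept point lies within ``radius`` mm.  Alternative to index
    striding when a metric sampling radius is wanted.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(cloud)
    if n == 0:
        return cloud.select([])
    tree = cKDTree(cloud.points)
    kept = np.zeros(n, dtype=bool)
    neighbor_lists = tree.query_ball_point(cloud.points, r=radius)
    for i in range(n):
        if not any(kept[j] for j in neighbor_lists[i] if j < i):
            kept[i] = True
    return cloud.select(kept)


def fit_axis_aligned_box(cloud: PointCloud) -> AxisAlignedBox:
    """Componentwise min/max box of a nonempty cloud (the six directional
    extremes front/back/left/right/up/down collapse to the two diagonal
    corners)."""
    if len(cloud) == 0:
        raise ValueError("cannot fit a box to an empty cloud")
    return AxisAlignedBox(cloud.points.min(axis=0), cloud.points.max(axis=0))


def fit_oriented_box(cloud: PointCloud) -> OrientedBox:
    """PCA-aligned oriented bounding box.

    Axes are the principal components of the centered points; extents come
    from the min/max projections.  Not the exact minimum-volume OBB, but
    deterministic and adequate for volume-ratio comparisons of the same
    leaf before/after smoothing.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise DegenerateGeometryError("oriented box needs >= 3 points")
    centered = pts - pts.mean(axis=0)
    # eigenvectors of the scatter matrix give the principal axes (and stay
    # coordinate-aligned for exactly isotropic point sets)
    evals, evecs = np.linalg.eigh(centered.T @ centered)
    vt = evecs[:, ::-1].T  # rows, descending variance
    if evals[1] <= 1e-18 * max(evals[2], 1e-300):
        raise DegenerateGeometryError("points are collinear; oriented box undefined")
    proj = centered @ vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    center = pts.mean(axis=0) + 0.5 * (lo + hi) @ vt
    return OrientedBox(center=center, axes=vt, half_extents=0.5 * (hi - lo))


def largest_component(cloud: PointCloud, radius: float) -> PointCloud:
    """Largest connected component of the cloud's ``radius``-neighborhood
    graph.  Used to isolate a leaf surface from spatially detached
    stragglers that landed in the same cluster."""
    from scipy.sparse.csgraph import connected_components

    n = len(cloud)
    if n == 0:
        return cloud
    tree = cKDTree(cloud.points)
    graph = tree.sparse_distance_matrix(tree, max_distance=radius, output_type="coo_matrix")
    _, labels = connected_components(graph.tocsr(), directed=False)
    counts = np.bincount(labels)
    return cloud.select(labels == counts.argmax())


def mean_nn_spacing(points: np.ndarray, sample: int = 2000, seed: int = 0) -> float:
    """Mean nearest-neighbor distance, estimated on a subsample for speed."""
    pts = np.asarray(points, float)
    n = len(pts)
    if n < 2:
        raise ValueError("need >= 2 points to estimate spacing")
    tree = cKDTree(pts)
    if n > sample:
        idx = np.random.default_rng(seed).choice(n, size=sample, replace=False)
        query = pts[idx]
    else:
        query = pts
    d, _ = tree.query(query, k=2)
    return float(d[:, 1].mean())
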