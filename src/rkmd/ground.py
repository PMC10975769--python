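"""Ground-plane removal: color-filtered, bounding-box-constrained RANSAC.

The idea: points with non-plant color are ground candidates; the dominant
plane is fitted by RANSAC on those candidates only, and its inliers —
restricted to the candidates' bounding box, so elevated plant parts are
never tested against the plane — are removed as ground.  The number of
stem points expected to fall inside the ground box is ``pi r^2 h rho``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import rgb_to_hsv

from .cloud import AxisAlignedBox, PointCloud, fit_axis_aligned_box


@dataclass(frozen=True)
class Plane:
    """Plane A x + B y + C z + D = 0 with unit normal (A, B, C)."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        norm = float(np.sqrt(self.a**2 + self.b**2 + self.c**2))
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("zero plane normal")
            object.__setattr__(self, "a", self.a / norm)
            object.__setattr__(self, "b", self.b / norm)
            object.__setattr__(self, "c", self.c / norm)
            object.__setattr__(self, "d", self.d / norm)

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned point-plane distance |A x + B y + C z + D| (normal is unit)."""
        p = np.atleast_2d(np.asarray(points, float))
        return np.abs(p @ self.normal + self.d)


@dataclass
class RansacConfig:
    """RANSAC parameters: inlier distance threshold (mm), iteration budget,
    early-exit inlier fraction, and the sampling seed."""

    distance_threshold: float = 1.0
    max_iterations: int = 500
    early_exit_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ColorRule:
    """Plant/ground color split in HSV: a point is *plant* iff its hue lies
    in [hue_min, hue_max] degrees and saturation >= sat_min; everything
    else is a ground candidate."""

    hue_min: float = 70.0
    hue_max: float = 170.0
    sat_min: float = 0.15


@dataclass
class GroundRemovalReport:
    """Counts from one removal run: points in the background box (NG),
    plane inliers removed, the fitted plane, and (when stem geometry is
    known) the expected number of stem points inside the box."""

    n_in_box: int
    inlier_count: int
    plane: Plane | None
    expected_stem_points: float | None = None
    ground_mask: np.ndarray | None = None  # per-input-point removal mask

    def __post_init__(self) -> None:
        if self.inlier_count > self.n_in_box:
            raise ValueError("inlier_count cannot exceed points in box")


class NoPlaneFoundError(RuntimeError):
    """All RANSAC samples were degenerate."""


def color_ground_filter(
    cloud: PointCloud, rule: ColorRule | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into (ground_candidates, rest) by the HSV color rule.

    The partition is exhaustive and disjoint.  Requires per-point colors.
    """
    if cloud.colors is None:
        raise ValueError("color_ground_filter requires per-point colors")
    rule = rule or ColorRule()
    if len(cloud) == 0:
        return np.zeros(0, np.int64), np.zeros(0, np.int64)
    hsv = rgb_to_hsv(cloud.colors)
    hue = hsv[:, 0] * 360.0
    plant = (hue >= rule.hue_min) & (hue <= rule.hue_max) & (hsv[:, 1] >= rule.sat_min)
    idx = np.arange(len(cloud))
    return idx[~plant], idx[plant]


def point_plane_distance(point, plane: Plane) -> float:
    """Distance |A x + B y + C z + D| from a single point to the plane."""
    return float(plane.distance(np.asarray(point, float).reshape(1, 3))[0])


def _plane_from_points(p1, p2, p3) -> Plane | None:
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        return None
    n = n / norm
    return Plane(n[0], n[1], n[2], -float(n @ p1))


def _lsq_plane(points: np.ndarray) -> Plane:
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    n = vt[-1]
    return Plane(n[0], n[1], n[2], -float(n @ centroid))


def ransac_plane(
    cloud: PointCloud | np.ndarray, config: RansacConfig, refit: bool = True
) -> tuple[Plane, np.ndarray]:
    """Fit the dominant plane by seeded RANSAC.

    Repeats {sample 3 distinct points, form their plane, count points with
    distance < threshold as inliers} for the iteration budget and keeps the
    plane with the most inliers (first-found wins on ties).  With ``refit``
    the winning inlier set gets a least-squares refit and the mask is
    recomputed against the refit plane.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float)
    n = len(pts)
    if n < 3:
        raise ValueError(f"ransac_plane needs >= 3 points, got {n}")
    rng = np.random.default_rng(config.seed)
    best_plane: Plane | None = None
    best_mask: np.ndarray | None = None
    best_count = -1
    for _ in range(config.max_iterations):
        i, j, k = rng.choice(n, size=3, replace=False)
        plane = _plane_from_points(pts[i], pts[j], pts[k])
        if plane is None:
            continue
        mask = plane.distance(pts) < config.distance_threshold
        count = int(mask.sum())
        if count > best_count:
            best_count, best_plane, best_mask = count, plane, mask
            if count >= config.early_exit_fraction * n:
                break
    if best_plane is None:
        raise NoPlaneFoundError("all sampled point triples were collinear")
    if refit and best_mask.sum() >= 3:
        refit_plane = _lsq_plane(pts[best_mask])
        refit_mask = refit_plane.distance(pts) < config.distance_threshold
        # keep the refit only if it does not lose consensus
        if refit_mask.sum() >= best_mask.sum():
            best_plane, best_mask = refit_plane, refit_mask
    return best_plane, best_mask


def remove_ground(
    cloud: PointCloud,
    config: RansacConfig | None = None,
    rule: ColorRule | None = None,
    stem_radius: float | None = None,
    stem_height: float | None = None,
    stem_point_density: float | None = None,
) -> tuple[PointCloud, PointCloud, GroundRemovalReport]:
    """Remove the ground plane from a colored scene cloud.

    Color-filters ground candidates, fits a RANSAC plane on them, and
    removes plane inliers inside the candidates' axis-aligned box.  Returns
    (plant, ground, report); |plant| + |ground| = |input| always.
    """
    config = config or RansacConfig()
    candidates, _rest = color_ground_filter(cloud, rule)
    if len(candidates) == 0:
        report = GroundRemovalReport(
            0, 0, None,
            _expected_stem(stem_radius, stem_height, stem_point_density),
            np.zeros(len(cloud), dtype=bool),
        )
        return cloud, cloud.select(np.zeros(0, np.int64)), report
    if len(candidates) < 3:
        raise ValueError(f"need >= 3 ground candidates to fit a plane, got {len(candidates)}")
    cand_cloud = cloud.select(candidates)
    box = fit_axis_aligned_box(cand_cloud)
    plane, _ = ransac_plane(cand_cloud, config)
    # Removal applies to the whole cloud, but only inside the candidate box
    # (pad by the distance threshold so boundary inliers are not missed).
    in_box = box.contains(cloud.points, pad=config.distance_threshold)
    ground_mask = in_box & (plane.distance(cloud.points) < config.distance_threshold)
    plant = cloud.select(~ground_mask)
    ground = cloud.select(ground_mask)
    report = GroundRemovalReport(
        n_in_box=int(in_box.sum()),
        inlier_count=int(ground_mask.sum()),
        plane=plane,
        expected_stem_points=_expected_stem(stem_radius, stem_height, stem_point_density),
        ground_mask=ground_mask,
    )
    return plant, ground, report


def _expected_stem(r, h, rho):
    if r is None or h is None or rho is None:
        return None
    return expected_stem_count(r, h, rho)


def expected_stem_count(r: float, h: float, rho_point: float) -> float:
    """Expected stem points in the ground box: pi * r^2 * h * rho."""
    if r < 0 or h < 0 or rho_point < 0:
        raise ValueError("stem radius, height and density must be nonnegative")
    return float(np.pi * r**2 * h * rho_point)


def threshold_sweep(
    cloud: PointCloud | np.ndarray,
    thresholds,
    seed: int = 0,
    max_iterations: int = 500,
) -> list[tuple[float, int]]:
    """Inlier count of the best RANSAC plane at each distance threshold —
    the tuning loop of gradually raising/lowering the threshold, as a table."""
    out = []
    for dt in thresholds:
        # full budget, no refit: counts stay comparable across thresholds
        cfg = RansacConfig(distance_threshold=float(dt), max_iterations=max_iterations,
                           seed=seed, early_exit_fraction=1.1)
        _, mask = ransac_plane(cloud, cfg, refit=False)
        out.append((float(dt), int(mask.sum())))
    return out
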