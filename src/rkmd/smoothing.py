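"""Per-leaf smoothing and smoothness accounting.

Moving-least-squares (MLS) smoothing fits a local plane or quadric in a
spherical neighborhood of each point, classifies points farther than an
inlier distance from the fitted surface as outliers, and projects outliers
back onto the surface along the local normal.

Smoothness of a leaf is the reciprocal of the mean angle (degrees) between
each point's normal and the normals of its 20 nearest neighbors: a mean
angle of 30 deg gives 0.033, 45 deg gives 0.022; larger is smoother.
Whether smoothing changed the leaf too much (or too little) is gated by
the ratio of oriented-bounding-box volumes before/after, accepted in
[0.7, 0.9].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import DegenerateGeometryError, PointCloud, fit_oriented_box, mean_nn_spacing

#: Neighbors used by the smoothness statistic and normal estimation.
SMOOTHNESS_NEIGHBORS = 20
#: Smoothness returned when every neighbor angle is zero (perfectly smooth).
SMOOTHNESS_CAP = 1e6

V_MIN = 0.7
V_MAX = 0.9


class InsufficientNeighborhoodError(ValueError):
    """A point's MLS ball holds too few neighbors for the surface fit."""


@dataclass
class MlsConfig:
    """MLS parameters: ball radius (mm; default 4x mean point spacing),
    local surface degree (1 plane, 2 quadric), and the inlier distance
    beyond which a point is projected (default radius / 10)."""

    radius: float | None = None
    surface_degree: int = 2
    inlier_distance: float | None = None

    def __post_init__(self) -> None:
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.surface_degree not in (1, 2):
            raise ValueError("surface_degree must be 1 or 2")
        if self.inlier_distance is not None and self.inlier_distance < 0:
            raise ValueError("inlier_distance must be nonnegative")

    def resolved(self, points: np.ndarray) -> tuple[float, float]:
        radius = self.radius if self.radius is not None else 4.0 * mean_nn_spacing(points)
        inlier = self.inlier_distance if self.inlier_distance is not None else radius / 10.0
        return radius, inlier


@dataclass
class SmoothnessReport:
    """Per-leaf smoothness rho_i and their average for one growth period."""

    per_leaf: list[float]
    average: float
    mean_angle_deg: float
    neighbor_count: int = SMOOTHNESS_NEIGHBORS


@dataclass
class VolumeRatioGate:
    """OBB volume ratio smoothed/original with the acceptance band."""

    ratio: float
    v_min: float = V_MIN
    v_max: float = V_MAX

    @property
    def passed(self) -> bool:
        return self.v_min <= self.ratio <= self.v_max


def estimate_normals(cloud: PointCloud, k: int = SMOOTHNESS_NEIGHBORS) -> np.ndarray:
    """Unit normals from a PCA plane fit over each point's k nearest
    neighbors, oriented away from the cloud centroid (ties broken +z)."""
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise ValueError("normal estimation needs >= 3 points")
    k = min(k, n - 1)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)
    nbrs = pts[idx]  # (n, k+1, 3), column 0 is the point itself
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nij,nik->njk", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # smallest-eigenvalue direction
    outward = pts - pts.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    ambiguous = np.abs(np.einsum("ij,ij->i", normals, outward)) < 1e-12
    flip |= ambiguous & (normals[:, 2] < 0)
    normals[flip] *= -1.0
    return normals


#: Cap on neighbors entering the local fit; the nearest ones within the
#: ball are kept when a neighborhood is larger (keeps the batched solve
#: bounded without changing the radius semantics for typical densities).
MLS_MAX_NEIGHBORS = 64


def _design_cols(u: np.ndarray, v: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(u), u, v]
    if degree == 2:
        cols += [u * u, u * v, v * v]
    return np.stack(cols, axis=-1)


def mls_smooth(leaf: PointCloud, config: MlsConfig | None = None) -> PointCloud:
    """MLS-smooth a leaf cloud; point count and attribute layout unchanged.

    For each point: gather neighbors inside the ball, fit the local plane
    or quadric in the neighborhood's PCA frame, and — if the point sits
    farther than the inlier distance from the fitted surface — project it
    onto the surface along the local normal.  Points already on their
    surface are untouched.  Raises
    :class:`InsufficientNeighborhoodError` if any point's ball cannot
    support even a plane fit.
    """
    config = config or MlsConfig()
    pts = leaf.points
    n = len(pts)
    if n < 6:
        raise ValueError(f"mls_smooth needs >= 6 points, got {n}")
    radius, inlier_distance = config.resolved(pts)
    tree = cKDTree(pts)
    k = min(MLS_MAX_NEIGHBORS, n)
    dist, idx = tree.query(pts, k=k)
    mask = dist <= radius
    counts = mask.sum(axis=1)
    if counts.min() < 3:
        worst = int(counts.argmin())
        raise InsufficientNeighborhoodError(
            f"point {worst}: only {int(counts[worst])} points within radius {radius:.3g} mm"
        )
    idx = np.where(mask, idx, idx[:, :1])  # pad with the point itself
    neigh = pts[idx]  # (n, k, 3)
    w = mask[..., None].astype(float)
    mu = (neigh * w).sum(axis=1) / counts[:, None]
    centered = (neigh - mu[:, None, :]) * w
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    frames = vecs[:, :, [2, 1, 0]].transpose(0, 2, 1)  # rows: t1, t2, normal
    local = np.einsum("nij,nkj->nki", frames, neigh - mu[:, None, :])
    p_local = np.einsum("nij,nj->ni", frames, pts - mu)
    out = pts.copy()
    quadric_ok = counts >= 6
    groups = [(1, ~quadric_ok)] if config.surface_degree == 2 else [(1, np.ones(n, bool))]
    if config.surface_degree == 2:
        groups.append((2, quadric_ok))
    for degree, sel in groups:
        if not sel.any():
            continue
        a = _design_cols(local[sel, :, 0], local[sel, :, 1], degree) * w[sel]
        rhs = local[sel, :, 2] * w[sel, :, 0]
        ata = np.einsum("nki,nkj->nij", a, a)
        atb = np.einsum("nki,nk->ni", a, rhs)
        # tiny ridge keeps near-degenerate in-plane layouts solvable
        ata += 1e-10 * np.eye(a.shape[-1])
        coeffs = np.linalg.solve(ata, atb[..., None])[..., 0]
        h = np.einsum(
            "ni,ni->n", _design_cols(p_local[sel, 0], p_local[sel, 1], degree), coeffs
        )
        residual = p_local[sel, 2] - h
        move = np.abs(residual) > inlier_distance
        target = pts[sel] - residual[:, None] * frames[sel, 2, :]
        rows = np.flatnonzero(sel)
        out[rows[move]] = target[move]
    return PointCloud(out, None if leaf.colors is None else leaf.colors.copy(), None)


def leaf_smoothness(
    leaf: PointCloud, neighbor_count: int = SMOOTHNESS_NEIGHBORS
) -> float:
    """Smoothness rho = 1 / (mean normal angle to the 20 NN, degrees).

    Uses the cloud's own normals when present, otherwise estimates them.
    Angles are folded to [0, 90] deg so orientation flips cannot fake
    roughness.  A perfectly smooth cloud (zero mean angle) returns the
    capped sentinel :data:`SMOOTHNESS_CAP`.
    """
    if len(leaf) < neighbor_count + 1:
        raise ValueError(f"smoothness needs >= {neighbor_count + 1} points, got {len(leaf)}")
    normals = leaf.normals if leaf.normals is not None else estimate_normals(leaf, neighbor_count)
    tree = cKDTree(leaf.points)
    _, idx = tree.query(leaf.points, k=neighbor_count + 1)
    nbr_normals = normals[idx[:, 1:]]  # exclude the point itself
    cosines = np.abs(np.einsum("ij,ikj->ik", normals, nbr_normals))
    angles = np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0)))
    mean_angle = float(angles.mean())
    if mean_angle <= 1.0 / SMOOTHNESS_CAP:
        return SMOOTHNESS_CAP
    return 1.0 / mean_angle


def average_smoothness(per_leaf: list[float]) -> float:
    """Arithmetic mean smoothness over the leaves of one period."""
    if not per_leaf:
        raise ValueError("average_smoothness needs at least one leaf")
    return float(np.mean(per_leaf))


def smoothness_report(leaves: list[PointCloud]) -> SmoothnessReport:
    per_leaf = [leaf_smoothness(leaf) for leaf in leaves]
    avg = average_smoothness(per_leaf)
    mean_angle = float("inf") if avg >= SMOOTHNESS_CAP else 1.0 / avg
    return SmoothnessReport(per_leaf=per_leaf, average=avg, mean_angle_deg=mean_angle)


def volume_ratio_gate(original: PointCloud, smoothed: PointCloud) -> VolumeRatioGate:
    """OBB volume ratio smoothed/original, accepted in [0.7, 0.9].

    A ratio near 1 means smoothing barely thinned the leaf; far below the
    band means it collapsed real structure.
    """
    vol_orig = fit_oriented_box(original).volume
    vol_smooth = fit_oriented_box(smoothed).volume
    if vol_orig <= 0:
        raise DegenerateGeometryError("original cloud has zero OBB volume")
    return VolumeRatioGate(ratio=vol_smooth / vol_orig)
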