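"""Euclidean-distance phenotype measurements: leaf length, perimeter, area.

* Length: project the leaf onto its measurement plane, connect the base
  and tip extremes by a chord, divide the chord into n1 equal parts, lift
  each division point back to the 3D surface, and sum the lifted polyline
  — an arc length that follows the leaf's curvature instead of the chord.
* Perimeter: downsample, extract the concave (alpha-shape) outline of the
  projected cloud, and sum consecutive 3D distances around the closed loop.
* Area: ball-pivot a triangle mesh over the cloud and sum triangle areas.

The measurement plane defaults to the leaf's own PCA plane (first two
principal axes), which keeps length well defined for steeply inclined
leaves; the literal fixed xy plane is available via ``plane="xy"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .ballpivot import ball_pivot_mesh, default_bpa_radii
from .cloud import DegenerateGeometryError, PointCloud, TriangleMesh, mean_nn_spacing, uniform_downsample

log = logging.getLogger(__name__)


class BoundaryExtractionError(RuntimeError):
    """The alpha-shape outline is degenerate or disconnected."""


def _grid_spacing(uv: np.ndarray) -> float:
    """Grid-equivalent point spacing sqrt(hull area / n) of 2D points —
    steadier than the mean NN distance under Poisson sampling gaps."""
    from scipy.spatial import ConvexHull

    if len(uv) < 3:
        raise DegenerateGeometryError("spacing needs >= 3 points")
    try:
        area = ConvexHull(uv).volume  # 2-D: volume is the area
    except Exception as exc:  # noqa: BLE001
        raise DegenerateGeometryError(f"degenerate 2-D projection: {exc}") from exc
    if area <= 0:
        raise DegenerateGeometryError("projected points are collinear")
    return float(np.sqrt(area / len(uv)))


@dataclass
class MeasureConfig:
    """Knobs of the three measurements.

    ``n1`` — chord subdivisions for length; ``length_scale`` (mu1) and
    ``area_scale`` (mu4) — calibration factors, 1 when coordinates are
    metric; ``downsample_every_k`` — striding before boundary extraction
    (``None`` = auto toward ~``target_boundary_points`` points);
    ``boundary_alpha`` — alpha-shape radius in mm (``None`` = 3x mean
    spacing of the downsampled cloud); ``bpa_radii`` — ascending ball
    radii in mm (``None`` = {2,3,4,5} x mean spacing); ``plane`` — "pca"
    or "xy".
    """

    n1: int = 50
    length_scale: float = 1.0
    area_scale: float = 1.0
    downsample_every_k: int | None = None
    # boundary discretization balances two errors: too fine and the trace
    # zigzags along sampling jitter (inflating the sum), too coarse and it
    # cuts corners; ~1500 outline-bearing points sits near the minimum for
    # leaf-sized clouds at realistic densities
    target_boundary_points: int = 1500
    boundary_alpha: float | None = None
    bpa_radii: list[float] | None = None
    plane: str = "pca"
    lift_radius_factor: float = 1.5
    # base/tip landmarks average this many extreme points, damping the
    # outward bias a single noise-displaced extreme would add to the length
    tip_landmark_points: int = 5

    def __post_init__(self) -> None:
        if self.n1 < 1:
            raise ValueError("n1 must be >= 1")
        if self.length_scale <= 0 or self.area_scale <= 0:
            raise ValueError("scales must be positive")
        if self.plane not in ("pca", "xy"):
            raise ValueError("plane must be 'pca' or 'xy'")
        if self.bpa_radii is not None:
            r = list(self.bpa_radii)
            if any(x <= 0 for x in r) or any(b <= a for a, b in zip(r, r[1:])):
                raise ValueError("bpa_radii must be positive and ascending")


@dataclass
class LeafMeasurement:
    """One leaf's measured length lp (mm), perimeter Cp (mm) and area Sp
    (mm^2), with the mesh/boundary sizes that produced them."""

    length: float
    perimeter: float
    area: float
    boundary_point_count: int = 0
    mesh_face_count: int = 0


def measurement_frame(leaf: PointCloud, plane: str = "pca") -> tuple[np.ndarray, np.ndarray]:
    """(origin, axes) of the measurement plane; axes rows are e1, e2, normal."""
    pts = leaf.points
    origin = pts.mean(axis=0)
    if plane == "xy":
        return origin, np.eye(3)
    if len(pts) < 3:
        raise DegenerateGeometryError("PCA plane needs >= 3 points")
    _, s, vt = np.linalg.svd(pts - origin, full_matrices=False)
    if s[0] <= 1e-12:
        raise DegenerateGeometryError("all points coincident")
    return origin, vt


def _project(leaf: PointCloud, plane: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    origin, axes = measurement_frame(leaf, plane)
    local = (leaf.points - origin) @ axes.T
    return local[:, :2], origin, axes


def identify_base_tip(
    leaf: PointCloud,
    plane: str = "pca",
    stem_reference: np.ndarray | None = None,
) -> tuple[int, int]:
    """Indices of the base and tip points: the extremes of the projected
    cloud along its first principal axis.  The base is the extreme nearer
    the stem reference when given, else the lower-z extreme (ties keep the
    axis-negative end, a fixed rule for symmetric clouds)."""
    if len(leaf) < 2:
        raise DegenerateGeometryError("base/tip needs >= 2 points")
    uv, _, _ = _project(leaf, plane)
    lo, hi = int(np.argmin(uv[:, 0])), int(np.argmax(uv[:, 0]))
    if uv[lo, 0] == uv[hi, 0]:
        raise DegenerateGeometryError("all points project to one location")
    p_lo, p_hi = leaf.points[lo], leaf.points[hi]
    if stem_reference is not None:
        ref = np.asarray(stem_reference, float)
        if np.linalg.norm(p_hi - ref) < np.linalg.norm(p_lo - ref):
            return hi, lo
        return lo, hi
    if p_hi[2] < p_lo[2]:
        return hi, lo
    return lo, hi


def leaf_length(
    leaf: PointCloud,
    config: MeasureConfig | None = None,
    stem_reference: np.ndarray | None = None,
) -> float:
    """Arc-style leaf length lp = mu1 * sum of lifted polyline segments.

    Division points of the base-tip chord are lifted to the surface as the
    centroid of cloud points within ``lift_radius_factor`` x mean spacing
    (in-plane); a division point with an empty lift corridor (a hole) is
    skipped and the segment bridged, with a log note.
    """
    config = config or MeasureConfig()
    if len(leaf) < 2:
        raise DegenerateGeometryError("leaf_length needs >= 2 points")
    origin, axes = measurement_frame(leaf, config.plane)
    local = (leaf.points - origin) @ axes.T  # (u, v, w): in-plane + height
    uv = local[:, :2]
    base, tip = identify_base_tip(leaf, config.plane, stem_reference)
    m = min(max(config.tip_landmark_points, 1), len(leaf))
    order = np.argsort(uv[:, 0], kind="stable")
    lo_set, hi_set = order[:m], order[-m:]
    if lo_set[0] != base and lo_set[0] == tip:  # base is the axis-high end
        lo_set, hi_set = hi_set, lo_set
    end_base, end_tip = local[lo_set].mean(axis=0), local[hi_set].mean(axis=0)
    lift_radius = config.lift_radius_factor * _grid_spacing(uv)
    tree2d = cKDTree(uv)
    # waypoints stay on the chord in-plane; only the height w is lifted to
    # the surface (mean height of the corridor points), so a flat leaf
    # yields exactly the chord for any n1
    waypoints = [end_base]
    chord = end_tip[:2] - end_base[:2]
    skipped = 0
    for i in range(1, config.n1):
        target = end_base[:2] + chord * (i / config.n1)
        corridor = tree2d.query_ball_point(target, lift_radius)
        if corridor:
            waypoints.append(np.append(target, local[corridor, 2].mean()))
        else:
            skipped += 1
    waypoints.append(end_tip)
    if skipped:
        log.warning("leaf_length: %d of %d division points had empty lift corridors (bridged)",
                    skipped, config.n1 - 1)
    poly = np.asarray(waypoints)
    return config.length_scale * float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())


def _alpha_boundary_loop(uv: np.ndarray, alpha: float) -> list[int]:
    """Boundary vertex loop of the 2D alpha complex (triangles with
    circumradius < alpha); returns the longest closed loop, as indices
    into uv."""
    if len(uv) < 3:
        raise BoundaryExtractionError("need >= 3 points for a boundary")
    try:
        tri = Delaunay(uv)
    except Exception as exc:  # noqa: BLE001 - qhull raises various types
        raise BoundaryExtractionError(f"degenerate projection: {exc}") from exc
    simplices = tri.simplices
    a = uv[simplices[:, 0]]
    b = uv[simplices[:, 1]]
    c = uv[simplices[:, 2]]
    la, lb, lc = (np.linalg.norm(b - c, axis=1), np.linalg.norm(a - c, axis=1),
                  np.linalg.norm(a - b, axis=1))
    cross = np.abs((b - a)[:, 0] * (c - a)[:, 1] - (b - a)[:, 1] * (c - a)[:, 0])
    circum = np.where(cross > 1e-12, la * lb * lc / np.where(cross > 1e-12, 2 * cross, 1.0), np.inf)
    kept = simplices[circum < alpha]
    if len(kept) == 0:
        raise BoundaryExtractionError(f"alpha {alpha:.3g} keeps no triangles")
    edge_count: dict[tuple[int, int], int] = {}
    for s in kept:
        for e in ((s[0], s[1]), (s[1], s[2]), (s[2], s[0])):
            key = (int(e[0]), int(e[1])) if e[0] < e[1] else (int(e[1]), int(e[0]))
            edge_count[key] = edge_count.get(key, 0) + 1
    boundary = [e for e, cnt in edge_count.items() if cnt == 1]
    if not boundary:
        raise BoundaryExtractionError("alpha complex has no boundary edges")
    adj: dict[int, list[int]] = {}
    for u, v in boundary:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    if any(len(nbrs) != 2 for nbrs in adj.values()):
        raise BoundaryExtractionError(
            "boundary is not a simple loop (alpha too small or outline self-intersects)"
        )
    # walk loops, keep the longest by polygon length
    unvisited = set(adj)
    best_loop: list[int] = []
    best_len = -1.0
    while unvisited:
        start = min(unvisited)
        loop = [start]
        prev, cur = None, start
        while True:
            nxt = [x for x in adj[cur] if x != prev]
            nxt = nxt[0] if nxt else prev
            if nxt == start:
                break
            loop.append(nxt)
            prev, cur = cur, nxt
        unvisited -= set(loop)
        length = float(np.linalg.norm(np.diff(uv[loop + [loop[0]]], axis=0), axis=1).sum())
        if length > best_len:
            best_len, best_loop = length, loop
    return best_loop


def extract_boundary(
    leaf: PointCloud, config: MeasureConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered boundary points of the leaf outline.

    Downsamples, projects to the measurement plane, extracts the concave
    alpha-shape outline and returns (boundary xyz array ordered clockwise
    when viewed against the plane normal, their indices into the
    downsampled cloud).
    """
    config = config or MeasureConfig()
    every_k = config.downsample_every_k
    if every_k is None:
        every_k = max(1, int(round(len(leaf) / config.target_boundary_points)))
    sub = uniform_downsample(leaf, every_k)
    if len(sub) < 3:
        raise BoundaryExtractionError("fewer than 3 points after downsampling")
    uv, _, _ = _project(sub, config.plane)
    if config.boundary_alpha is not None:
        loop = _alpha_boundary_loop(uv, config.boundary_alpha)
    else:
        # auto alpha: start at 3x the grid-equivalent spacing and grow until
        # the outline closes into a simple loop (Poisson gaps can exceed the
        # nominal spacing considerably)
        alpha = 3.0 * _grid_spacing(uv)
        last_exc: Exception | None = None
        loop = None
        for _ in range(6):
            try:
                loop = _alpha_boundary_loop(uv, alpha)
                break
            except BoundaryExtractionError as exc:
                last_exc = exc
                alpha *= 1.5
        if loop is None:
            raise BoundaryExtractionError(f"auto alpha failed up to {alpha:.3g}: {last_exc}")
    # clockwise against the plane normal: negative signed area in (e1, e2)
    poly = uv[loop]
    signed = 0.5 * float(
        np.sum(poly[:, 0] * np.roll(poly[:, 1], -1) - np.roll(poly[:, 0], -1) * poly[:, 1])
    )
    if signed > 0:
        loop = loop[::-1]
    loop_idx = np.asarray(loop, dtype=np.int64)
    return sub.points[loop_idx], loop_idx


def leaf_perimeter(boundary: np.ndarray, length_scale: float = 1.0) -> float:
    """Perimeter Cp = mu1 * sum of consecutive 3D distances around the
    closed boundary loop (last point connects back to the first)."""
    pts = np.asarray(boundary, float)
    if len(pts) < 3:
        raise ValueError(f"perimeter needs >= 3 boundary points, got {len(pts)}")
    closed = np.vstack([pts, pts[:1]])
    return length_scale * float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def triangle_area(v1, v2, v3) -> float:
    """Half the cross-product norm of two edge vectors (0 when collinear)."""
    v1, v2, v3 = (np.asarray(v, float) for v in (v1, v2, v3))
    return 0.5 * float(np.linalg.norm(np.cross(v2 - v1, v3 - v1)))


def leaf_area(mesh: TriangleMesh, area_scale: float = 1.0) -> float:
    """Area Sp = mu4 * sum of triangle areas over the mesh."""
    if len(mesh) == 0:
        raise ValueError("leaf_area needs a nonempty mesh")
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return area_scale * 0.5 * float(np.linalg.norm(cross, axis=1).sum())


def measure_leaf(
    leaf: PointCloud,
    config: MeasureConfig | None = None,
    stem_reference: np.ndarray | None = None,
) -> LeafMeasurement:
    """Run all three measurements on one (smoothed) leaf cloud."""
    config = config or MeasureConfig()
    length = leaf_length(leaf, config, stem_reference)
    boundary, _ = extract_boundary(leaf, config)
    perimeter = leaf_perimeter(boundary, config.length_scale)
    radii = config.bpa_radii if config.bpa_radii is not None else default_bpa_radii(leaf.points)
    mesh = ball_pivot_mesh(leaf, radii)
    area = leaf_area(mesh, config.area_scale)
    return LeafMeasurement(
        length=length,
        perimeter=perimeter,
        area=area,
        boundary_point_count=len(boundary),
        mesh_face_count=len(mesh),
    )
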