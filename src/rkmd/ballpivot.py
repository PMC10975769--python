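"""Ball-pivoting surface reconstruction.

A ball of radius r rests on three points (its seed triangle), then pivots
around each front edge: rotating about the edge, the first point it
touches forms a new triangle.  Radii are applied in ascending order, so
small balls triangulate dense regions first and larger balls fill the
sparser gaps left behind — the multi-radius policy that reduces holes.

Mesh vertices are always input points.  Normals (estimated if absent,
oriented consistently against the cloud's minor principal axis — adequate
for leaf-like sheets that bend less than a quarter turn) pick the side the
ball rolls on and fix the triangle winding.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud, TriangleMesh, mean_nn_spacing
from .smoothing import estimate_normals

_ON_BALL_TOL = 1e-7  # relative shell tolerance for the empty-ball test
_SEED_NEIGHBORS = 24


class ReconstructionFailureError(RuntimeError):
    """No triangle could be seeded at any radius."""


def default_bpa_radii(points: np.ndarray, factors=(2.0, 3.0, 4.0, 5.0)) -> list[float]:
    """Spacing-relative ball radii: factors x mean nearest-neighbor spacing."""
    s = mean_nn_spacing(points)
    return [float(f) * s for f in factors]


def _oriented_normals(leaf: PointCloud) -> np.ndarray:
    if leaf.normals is not None:
        return leaf.normals
    normals = estimate_normals(leaf)
    centered = leaf.points - leaf.points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    ref = vt[-1]
    if (normals @ ref < 0).mean() > 0.5:
        ref = -ref
    normals[normals @ ref < 0] *= -1.0
    return normals


def _ball_centers(pa, pb, pc_arr, r):
    """Vectorized centers of balls of radius r through edge (pa, pb) and
    each candidate point.  Returns (centers_plus, centers_minus, tri_normal,
    valid mask); invalid where the circumradius exceeds r or the triangle
    is degenerate."""
    e1 = pb - pa
    e2 = pc_arr - pa
    n = np.cross(np.broadcast_to(e1, e2.shape), e2)
    n2 = np.einsum("ij,ij->i", n, n)
    valid = n2 > 1e-24
    n2safe = np.where(valid, n2, 1.0)
    l1 = float(e1 @ e1)
    l2 = np.einsum("ij,ij->i", e2, e2)
    # circumcenter = pa + (l2 * (n x e1) + l1 * (e2 x n)) / (2 |n|^2)
    c = pa + (l2[:, None] * np.cross(n, e1) + l1 * np.cross(e2, n)) / (2.0 * n2safe[:, None])
    rc2 = np.einsum("ij,ij->i", c - pa, c - pa)
    h2 = r * r - rc2
    valid &= h2 > 0
    h = np.sqrt(np.where(valid, h2, 0.0))
    n_unit = n / np.sqrt(n2safe)[:, None]
    return c + h[:, None] * n_unit, c - h[:, None] * n_unit, n_unit, valid


class _BpaState:
    def __init__(self, points: np.ndarray, normals: np.ndarray):
        self.pts = points
        self.normals = normals
        self.tree = cKDTree(points)
        self.faces: list[tuple[int, int, int]] = []
        self.face_set: set[tuple[int, int, int]] = set()
        self.edge_count: dict[tuple[int, int], int] = {}
        self.edge_data: dict[tuple[int, int], tuple[int, int, int, np.ndarray]] = {}
        self.front: deque[tuple[int, int]] = deque()
        self.frozen: set[tuple[int, int]] = set()  # failed at the current radius
        self.used = np.zeros(len(points), dtype=bool)

    def ball_empty(self, center: np.ndarray, r: float) -> bool:
        return not self.tree.query_ball_point(center, r * (1.0 - _ON_BALL_TOL), return_length=True)

    def add_triangle(self, i: int, j: int, k: int, center: np.ndarray) -> None:
        """Record triangle wound (i, j, k); push its edges on the front."""
        key = tuple(sorted((i, j, k)))
        self.face_set.add(key)
        self.faces.append((i, j, k))
        self.used[[i, j, k]] = True
        for a, b, opp in ((i, j, k), (j, k, i), (k, i, j)):
            ekey = (a, b) if a < b else (b, a)
            cnt = self.edge_count.get(ekey, 0) + 1
            self.edge_count[ekey] = cnt
            if cnt == 1:
                self.edge_data[ekey] = (a, b, opp, center)
                self.front.append(ekey)
                self.frozen.discard(ekey)
            else:
                self.edge_data.pop(ekey, None)
                self.frozen.discard(ekey)

    def pivot(self, ekey: tuple[int, int], r: float) -> bool:
        """Pivot the ball around a front edge; returns True if a triangle
        was added."""
        a, b, opp, c_old = self.edge_data[ekey]
        pa, pb = self.pts[a], self.pts[b]
        m = 0.5 * (pa + pb)
        half2 = float(np.einsum("i,i->", pb - pa, pb - pa)) / 4.0
        if half2 >= r * r:
            return False  # edge longer than the ball diameter
        rho = np.sqrt(r * r - half2)
        cand = self.tree.query_ball_point(m, rho + r)
        cand = np.array([x for x in cand if x not in (a, b, opp)], dtype=np.int64)
        if len(cand) == 0:
            return False
        cp, cm, _, valid = _ball_centers(pa, pb, self.pts[cand], r)
        axis = (pb - pa) / np.linalg.norm(pb - pa)
        v_old = c_old - m
        events = []
        for centers in (cp, cm):
            v = centers - m
            sin_t = np.einsum("ij,j->i", np.cross(np.broadcast_to(v_old, v.shape), v), axis)
            cos_t = np.einsum("ij,j->i", v, v_old)
            theta = np.mod(np.arctan2(sin_t, cos_t), 2.0 * np.pi)
            events.append(np.where(valid, theta, np.inf))
        theta_all = np.concatenate(events)
        centers_all = np.vstack([cp, cm])
        cand_all = np.concatenate([cand, cand])
        order = np.argsort(theta_all, kind="stable")
        for pos in order:
            if not np.isfinite(theta_all[pos]) or theta_all[pos] < 1e-9:
                continue
            x = int(cand_all[pos])
            center = centers_all[pos]
            tri_key = tuple(sorted((a, b, x)))
            if tri_key in self.face_set:
                return False  # would re-create an existing face: edge is done
            e1 = (a, x) if a < x else (x, a)
            e2 = (b, x) if b < x else (x, b)
            if self.edge_count.get(e1, 0) >= 2 or self.edge_count.get(e2, 0) >= 2:
                continue
            if not self.ball_empty(center, r):
                continue
            # new triangle on the far side of (a -> b), wound (b, a, x)
            self.add_triangle(b, a, x, center)
            return True
        return False

    def find_seed(self, r: float, start: int) -> tuple[int, bool]:
        """Scan for a seed triangle among unused points from index ``start``.
        Returns (next start index, seeded?)."""
        n = len(self.pts)
        for i in range(start, n):
            if self.used[i]:
                continue
            nbr_idx, nbr_d = self._neighbors_sorted(i, 2.0 * r)
            nbr_idx = nbr_idx[~self.used[nbr_idx]][:_SEED_NEIGHBORS]
            if len(nbr_idx) < 2:
                continue
            pa = self.pts[i]
            for jpos in range(len(nbr_idx)):
                j = int(nbr_idx[jpos])
                rest = nbr_idx[jpos + 1 :]
                if len(rest) == 0:
                    continue
                cp, cm, tri_n, valid = _ball_centers(pa, self.pts[j], self.pts[rest], r)
                if not valid.any():
                    continue
                avg_n = self.normals[i] + self.normals[j] + self.normals[rest]
                side = np.einsum("ij,ij->i", tri_n, avg_n)
                centers = np.where(side[:, None] >= 0, cp, cm)
                for kpos in np.flatnonzero(valid):
                    k = int(rest[kpos])
                    if not self.ball_empty(centers[kpos], r):
                        continue
                    # wind the seed so its normal follows the vertex normals
                    if side[kpos] >= 0:
                        self.add_triangle(i, j, k, centers[kpos])
                    else:
                        self.add_triangle(i, k, j, centers[kpos])
                    return i, True
        return n, False

    def _neighbors_sorted(self, i: int, radius: float):
        idx = np.array(self.tree.query_ball_point(self.pts[i], radius), dtype=np.int64)
        idx = idx[idx != i]
        d = np.linalg.norm(self.pts[idx] - self.pts[i], axis=1)
        order = np.argsort(d, kind="stable")
        return idx[order], d[order]


def ball_pivot_mesh(
    leaf: PointCloud, radii: list[float] | None = None
) -> TriangleMesh:
    """Reconstruct a triangle mesh by multi-radius ball pivoting.

    ``radii`` must be ascending; the default is {2, 3, 4, 5} x the mean
    nearest-neighbor spacing.  Raises
    :class:`ReconstructionFailureError` if no triangle can be seeded.
    """
    pts = leaf.points
    if len(pts) < 3:
        raise ValueError(f"ball pivoting needs >= 3 points, got {len(pts)}")
    if radii is None:
        radii = default_bpa_radii(pts)
    radii = [float(r) for r in radii]
    if any(r <= 0 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be positive and strictly ascending")
    normals = _oriented_normals(leaf)
    state = _BpaState(pts, normals)
    for r in radii:
        # previously failed edges get another chance with the larger ball
        state.front.extend(state.frozen)
        state.frozen.clear()
        seed_cursor = 0
        while True:
            while state.front:
                ekey = state.front.popleft()
                if ekey not in state.edge_data or ekey in state.frozen:
                    continue
                if not state.pivot(ekey, r):
                    if ekey in state.edge_data:
                        state.frozen.add(ekey)
            seed_cursor, seeded = state.find_seed(r, seed_cursor)
            if not seeded:
                break
    if not state.faces:
        raise ReconstructionFailureError(
            f"no seed triangle found at radii {radii} over {len(pts)} points"
        )
    return TriangleMesh(pts, np.asarray(state.faces, dtype=np.int64))
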