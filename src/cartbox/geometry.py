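"""Low-level geometric primitives used by the mesh and registration layers.

Everything here is exact (up to floating point): closest-point queries
evaluate every candidate triangle analytically, and containment uses
the generalized winding number, which is robust for watertight meshes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MeshProximity",
    "closest_point_on_triangles",
    "closest_point_on_mesh",
    "winding_number",
    "segment_index",
    "N_SEGMENTS",
]

N_SEGMENTS = 80
_TWO_PI = 2.0 * np.pi


def segment_index(theta: np.ndarray, n_segments: int = N_SEGMENTS) -> np.ndarray:
    """Circumferential segment index for polar angle(s) ``theta`` (radians).

    Segment 0 starts at the +x axis (anterior-septal junction); indices
    increase counterclockwise as seen from the apex, which in the
    package frame (apex at low z, viewed looking toward +z) is the
    clockwise direction of the mathematical angle.
    """
    k = np.floor(np.mod(-np.asarray(theta), _TWO_PI) / (_TWO_PI / n_segments))
    return np.minimum(k.astype(int), n_segments - 1)


def _closest_on_segment(p, a, b):
    """Closest points to ``p`` on segments a->b (all (..., 3) arrays)."""
    ab = b - a
    denom = np.einsum("...i,...i", ab, ab)
    t = np.einsum("...i,...i", p - a, ab) / np.where(denom == 0.0, 1.0, denom)
    t = np.clip(t, 0.0, 1.0)[..., None]
    return a + t * ab


def _closest_on_triangles_batch(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest point on triangles, broadcast over leading axes.

    ``p`` has shape (..., 3) and ``tri`` shape (..., m, 3, 3); returns
    squared distances (..., m) and closest points (..., m, 3).  The
    closest point is the in-plane projection when its barycentric
    coordinates are non-negative, otherwise the best edge projection.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    e0, e1 = b - a, c - a
    w = p[..., None, :] - a
    aa = np.einsum("...i,...i", e0, e0)
    bb = np.einsum("...i,...i", e0, e1)
    cc = np.einsum("...i,...i", e1, e1)
    d0 = np.einsum("...i,...i", e0, w)
    d1 = np.einsum("...i,...i", e1, w)
    det = aa * cc - bb * bb
    det_safe = np.where(det <= 0.0, 1.0, det)
    s = (cc * d0 - bb * d1) / det_safe
    t = (aa * d1 - bb * d0) / det_safe
    interior = (s >= 0.0) & (t >= 0.0) & (s + t <= 1.0) & (det > 0.0)
    foot = a + s[..., None] * e0 + t[..., None] * e1

    pp = p[..., None, :]
    cand = np.stack(
        [
            np.where(interior[..., None], foot, np.inf),
            _closest_on_segment(pp, a, b),
            _closest_on_segment(pp, b, c),
            _closest_on_segment(pp, c, a),
        ],
        axis=-2,
    )  # (..., m, 4, 3)
    diff = cand - pp[..., None, :]
    d2 = np.einsum("...i,...i", diff, diff)  # (..., m, 4)
    best = np.argmin(d2, axis=-1)
    d2_best = np.take_along_axis(d2, best[..., None], axis=-1)[..., 0]
    foot_best = np.take_along_axis(cand, best[..., None, None], axis=-2)[..., 0, :]
    return d2_best, foot_best


def closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest point to ``p`` (3,) on each triangle of ``tri`` (m, 3, 3).

    Returns ``(distances (m,), closest points (m, 3))``.
    """
    d2, foot = _closest_on_triangles_batch(np.asarray(p, dtype=float), tri)
    return np.sqrt(d2), foot


class MeshProximity:
    """Exact closest-surface queries with a provably safe KD-tree prune.

    Candidates per query point are the k nearest triangle centroids
    plus every oversized triangle (e.g. the apex fan); the result is
    provably exact whenever the k-th centroid lies farther than the
    best distance found plus the largest remaining triangle radius,
    and the rare points violating that bound are rescanned with a ball
    query.  Results equal an exhaustive all-triangle scan.
    """

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray):
        from scipy.spatial import cKDTree

        tri = vertices[triangles].astype(float)  # (m, 3, 3)
        self.tri = tri
        self._a = tri[:, 0]
        self._e0 = tri[:, 1] - tri[:, 0]
        self._e1 = tri[:, 2] - tri[:, 0]
        self._aa = np.einsum("ij,ij->i", self._e0, self._e0)
        self._bb = np.einsum("ij,ij->i", self._e0, self._e1)
        self._cc = np.einsum("ij,ij->i", self._e1, self._e1)
        det = self._aa * self._cc - self._bb**2
        self._det_ok = det > 0.0
        self._det_safe = np.where(self._det_ok, det, 1.0)

        self._centroids = tri.mean(axis=1)
        radii = np.linalg.norm(tri - self._centroids[:, None, :], axis=2).max(axis=1)
        big = radii > 2.0 * np.median(radii)
        self._big_idx = np.nonzero(big)[0]
        self._r_small = float(radii[~big].max()) if np.any(~big) else 0.0
        self._vtree = cKDTree(vertices)
        self._ctree = cKDTree(self._centroids)

    def _eval(self, points: np.ndarray, idx: np.ndarray):
        """Exact squared distance and foot point per (point, candidate)."""
        a = self._a[idx]
        e0 = self._e0[idx]
        e1 = self._e1[idx]
        w = points[:, None, :] - a
        d0 = np.einsum("nkj,nkj->nk", e0, w)
        d1 = np.einsum("nkj,nkj->nk", e1, w)
        det_safe = self._det_safe[idx]
        s = (self._cc[idx] * d0 - self._bb[idx] * d1) / det_safe
        t = (self._aa[idx] * d1 - self._bb[idx] * d0) / det_safe
        interior = (s >= 0.0) & (t >= 0.0) & (s + t <= 1.0) & self._det_ok[idx]
        foot = a + s[..., None] * e0 + t[..., None] * e1
        diff = foot - points[:, None, :]
        d2 = np.where(interior, np.einsum("nkj,nkj->nk", diff, diff), np.inf)

        # edge candidates: a->b (e0), a->c (e1), b->c (e1 - e0)
        for base, vec, vv in (
            (a, e0, self._aa[idx]),
            (a, e1, self._cc[idx]),
            (a + e0, e1 - e0, self._aa[idx] + self._cc[idx] - 2 * self._bb[idx]),
        ):
            wt = np.einsum("nkj,nkj->nk", points[:, None, :] - base, vec)
            tt = np.clip(wt / np.where(vv <= 0.0, 1.0, vv), 0.0, 1.0)
            cand = base + tt[..., None] * vec
            diff = cand - points[:, None, :]
            d2_e = np.einsum("nkj,nkj->nk", diff, diff)
            better = d2_e < d2
            d2 = np.where(better, d2_e, d2)
            foot = np.where(better[..., None], cand, foot)
        return d2, foot

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        m = len(self.tri)
        k = min(24, m)
        cdist, cidx = self._ctree.query(points, k=k)
        cdist = np.atleast_2d(cdist)
        cidx = np.atleast_2d(cidx)
        if len(self._big_idx):
            cidx = np.concatenate(
                [cidx, np.broadcast_to(self._big_idx, (n, len(self._big_idx)))], axis=1
            )

        d2, foots = self._eval(points, cidx)
        j = np.argmin(d2, axis=1)
        rows = np.arange(n)
        dist = np.sqrt(d2[rows, j])
        foot = foots[rows, j]
        tidx = cidx[rows, j]

        unsafe = np.nonzero((k < m) & (cdist[:, k - 1] < dist + self._r_small + 1e-9))[0]
        for i in unsafe:
            cand = np.asarray(
                self._ctree.query_ball_point(points[i], dist[i] + self._r_small + 1e-9),
                dtype=int,
            )
            if len(cand) == 0:
                continue
            d2_i, f_i = self._eval(points[i][None, :], cand[None, :])
            jj = int(np.argmin(d2_i[0]))
            if d2_i[0, jj] < dist[i] ** 2:
                dist[i] = np.sqrt(d2_i[0, jj])
                foot[i] = f_i[0, jj]
                tidx[i] = int(cand[jj])
        return dist, foot, tidx


def closest_point_on_mesh(
    points: np.ndarray, vertices: np.ndarray, triangles: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest surface point on a triangle mesh for each query point.

    Returns ``(distance (n,), foot point (n, 3), triangle index (n,))``;
    equal to an exhaustive scan over every triangle.
    """
    return MeshProximity(vertices, triangles).query(points)


def winding_number(points: np.ndarray, vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Generalized winding number of each point w.r.t. a closed mesh.

    Computed as the sum of signed solid angles (van Oosterom &
    Strackee).  ~1 inside a watertight, outward-oriented surface,
    ~0 outside.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = vertices[triangles]
    out = np.empty(len(points))
    for i, p in enumerate(points):
        a = tri[:, 0] - p
        b = tri[:, 1] - p
        c = tri[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("ij,ij->i", a, b) * lc
            + np.einsum("ij,ij->i", b, c) * la
            + np.einsum("ij,ij->i", c, a) * lb
        )
        out[i] = np.sum(2.0 * np.arctan2(num, den)) / (4.0 * np.pi)
    return out
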