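"""Endocardial surface ("cine") mesh: construction and queries.

The mesh is built by resampling each slice's end-diastolic endocardial
contour to a fixed number of equal-arclength points, stitching adjacent
rings with triangles and closing the apex with a fan to the centroid of
the most apical ring.  The result is an open surface whose single
boundary loop is the basal ring; containment queries use a copy capped
at the base so that anything on the atrial side of the basal plane
(e.g. the LV outflow tract) counts as outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

from .errors import GeometryError
from .geometry import N_SEGMENTS, segment_index, winding_number
from .io import ContourStack

__all__ = [
    "SurfaceMesh",
    "build_endocardial_mesh",
    "closest_surface_distance",
    "is_inside_lv",
    "project_scalar_field",
    "endocardial_segment_areas",
]


@dataclass
class SurfaceMesh:
    """Triangulated LV endocardial surface (mm).

    ``basal_plane`` is (point, unit normal) with the normal pointing
    away from the apex (toward the atria); ``slice_of_vertex`` maps
    each vertex to the contour slice (ring) it came from, the apex
    vertex inheriting the most apical slice index.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    basal_plane: tuple
    apex_vertex: int
    slice_of_vertex: np.ndarray
    vertex_channels: dict = field(default_factory=dict)
    points_per_ring: int = N_SEGMENTS

    _capped: tuple | None = field(default=None, repr=False, compare=False)
    _proximity: object | None = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_rings(self) -> int:
        return int(self.slice_of_vertex.max()) + 1

    @property
    def apex(self) -> np.ndarray:
        return self.vertices[self.apex_vertex]

    @property
    def basal_centroid(self) -> np.ndarray:
        return self.vertices[: self.points_per_ring].mean(axis=0)

    @property
    def long_axis(self) -> np.ndarray:
        """Unit vector from apex toward the basal-ring centroid."""
        v = self.basal_centroid - self.apex
        return v / np.linalg.norm(v)

    @property
    def area(self) -> float:
        tri = self.vertices[self.triangles]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def triangle_areas(self) -> np.ndarray:
        tri = self.vertices[self.triangles]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def edges(self) -> np.ndarray:
        """Undirected unique edges (m, 2)."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def vertex_adjacency(self) -> list:
        adj = [[] for _ in range(self.n_vertices)]
        for a, b in self.edges():
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def closest(self, points: np.ndarray):
        """Vectorized closest-surface query: (dist, foot, triangle index)."""
        if len(self.triangles) == 0:
            raise GeometryError("empty mesh")
        if self._proximity is None:
            from .geometry import MeshProximity

            self._proximity = MeshProximity(self.vertices, self.triangles)
        return self._proximity.query(points)

    def _capped_arrays(self):
        # cap the basal boundary loop with a fan to its centroid
        if self._capped is None:
            n = self.points_per_ring
            verts = np.vstack([self.vertices, self.basal_centroid[None, :]])
            cidx = len(verts) - 1
            k = np.arange(n)
            # basal ring is CCW seen from +z; fan oriented outward (+z side)
            cap = np.column_stack([k, (k + 1) % n, np.full(n, cidx)])
            tris = np.vstack([self.triangles, cap])
            self._capped = (verts, tris)
        return self._capped

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True for points inside the basally-capped endocardial volume."""
        verts, tris = self._capped_arrays()
        w = winding_number(points, verts, tris)
        return np.abs(w) > 0.5

    def with_channel(self, name: str, values: np.ndarray) -> "SurfaceMesh":
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_vertices,):
            raise GeometryError("channel length must equal vertex count")
        channels = dict(self.vertex_channels)
        channels[name] = values
        return SurfaceMesh(
            vertices=self.vertices,
            triangles=self.triangles,
            basal_plane=self.basal_plane,
            apex_vertex=self.apex_vertex,
            slice_of_vertex=self.slice_of_vertex,
            vertex_channels=channels,
            points_per_ring=self.points_per_ring,
        )

    def transformed(self, transform) -> "SurfaceMesh":
        """Mesh with vertices mapped by a rigid transform."""
        point, normal = self.basal_plane
        rot = transform.rotation_matrix
        return SurfaceMesh(
            vertices=transform.apply(self.vertices),
            triangles=self.triangles,
            basal_plane=(transform.apply(point[None, :])[0], rot @ normal),
            apex_vertex=self.apex_vertex,
            slice_of_vertex=self.slice_of_vertex,
            vertex_channels={k: v.copy() for k, v in self.vertex_channels.items()},
            points_per_ring=self.points_per_ring,
        )


def _resample_ring(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed 2D polygon to ``n`` equal-arclength points.

    Output is oriented counterclockwise in the xy plane (seen from +z,
    i.e. from the base) and starts at the polygon's first vertex.
    """
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise GeometryError("degenerate (zero-length) contour ring")
    # signed area (shoelace); enforce CCW
    x, y = poly[:, 0], poly[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if abs(signed) < 1e-9:
        raise GeometryError("degenerate (zero-area) contour ring")
    if signed < 0:
        poly = poly[::-1]
        closed = np.vstack([poly, poly[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n) * total / n
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] == 0, 1.0, seg[idx])
    return closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])


def _align_ring(ring: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Cyclically shift ``ring`` to minimize summed distance to ``ref``."""
    n = len(ring)
    costs = np.empty(n)
    for s in range(n):
        costs[s] = np.sum((np.roll(ring, -s, axis=0) - ref) ** 2)
    return np.roll(ring, -int(np.argmin(costs)), axis=0)


def build_endocardial_mesh(stack: ContourStack, points_per_ring: int = N_SEGMENTS) -> SurfaceMesh:
    """Build the end-diastolic endocardial surface mesh from a contour stack.

    Each slice's ``endo_ed`` polygon is resampled to ``points_per_ring``
    equal-arclength points; rings are angularly aligned by a discrete
    rotation search to avoid twisted stitching; adjacent rings are
    joined with ``2 * points_per_ring`` triangles and the apex is closed
    with a fan to the centroid of the most apical ring (which becomes
    the apex vertex).  Triangles are wound so normals point outward,
    away from the cavity.
    """
    stack.validate()
    if stack.n_slices < 3:
        raise GeometryError("need at least 3 slices to build a mesh")
    if points_per_ring < 16:
        raise GeometryError("points_per_ring must be >= 16")
    n = points_per_ring
    rings = []
    for s in stack.slices:
        ring2d = _resample_ring(s.endo_ed, n)
        if rings:
            ring2d = _align_ring(ring2d, rings[-1][:, :2])
        rings.append(np.column_stack([ring2d, np.full(n, s.z_mm)]))

    n_slices = len(rings)
    vertices = np.vstack(rings)
    apex = rings[-1].mean(axis=0)
    vertices = np.vstack([vertices, apex[None, :]])
    apex_vertex = len(vertices) - 1

    tris = []
    k = np.arange(n)
    kn = (k + 1) % n
    for s in range(n_slices - 1):
        u, l = s * n, (s + 1) * n
        # outward winding for CCW rings stacked base (high z) -> apex
        tris.append(np.column_stack([u + k, l + k, l + kn]))
        tris.append(np.column_stack([u + k, l + kn, u + kn]))
    last = (n_slices - 1) * n
    tris.append(np.column_stack([last + k, np.full(n, apex_vertex), last + kn]))
    triangles = np.vstack(tris)

    slice_of_vertex = np.repeat(np.arange(n_slices), n)
    slice_of_vertex = np.concatenate([slice_of_vertex, [n_slices - 1]])

    basal_centroid = rings[0].mean(axis=0)
    normal = basal_centroid - apex
    normal = normal / np.linalg.norm(normal)

    return SurfaceMesh(
        vertices=vertices,
        triangles=triangles,
        basal_plane=(basal_centroid, normal),
        apex_vertex=apex_vertex,
        slice_of_vertex=slice_of_vertex,
        points_per_ring=n,
    )


def closest_surface_distance(p: np.ndarray, mesh: SurfaceMesh):
    """Exact closest distance from a point to the mesh surface.

    Returns ``(distance_mm, foot_point, triangle_index)``.
    """
    d, f, t = mesh.closest(np.asarray(p, dtype=float)[None, :])
    return float(d[0]), f[0], int(t[0])


def is_inside_lv(p: np.ndarray, mesh: SurfaceMesh) -> bool:
    """Whether a point lies inside the basally-capped LV cavity.

    Points on the atrial side of the basal plane are outside by
    construction of the cap.
    """
    return bool(mesh.contains(np.asarray(p, dtype=float)[None, :])[0])


def project_scalar_field(
    sample_positions: np.ndarray,
    sample_values: np.ndarray,
    mesh: SurfaceMesh,
    channel: str,
) -> SurfaceMesh:
    """Project scattered (position, value) samples onto mesh vertices.

    Linear scattered interpolation inside the samples' convex hull;
    vertices outside the hull take the nearest sample's value.  The
    interpolated values are stored as a named per-vertex channel on a
    copy of the mesh.
    """
    pos = np.asarray(sample_positions, dtype=float)
    val = np.asarray(sample_values, dtype=float)
    if len(pos) < 4:
        raise GeometryError("need at least 4 scattered samples")
    try:
        lin = LinearNDInterpolator(pos, val)
    except QhullError as exc:
        raise GeometryError(f"samples are degenerate (coplanar?): {exc}") from exc
    out = lin(mesh.vertices)
    nan = ~np.isfinite(out)
    if np.any(nan):
        out[nan] = NearestNDInterpolator(pos, val)(mesh.vertices[nan])
    return mesh.with_channel(channel, out)


def endocardial_segment_areas(mesh: SurfaceMesh, n_segments: int = N_SEGMENTS) -> np.ndarray:
    """Endocardial surface area (cm^2) per (slice, circumferential segment).

    Triangle areas are accumulated into the bullseye cell of their
    centroid: the slice row is the band between rings (the apex fan
    accrues to the most apical row), the segment from the centroid's
    polar angle about the band's ring centre.
    """
    n = mesh.points_per_ring
    n_rings = mesh.n_rings
    areas = np.zeros((n_rings, n_segments))
    tri = mesh.vertices[mesh.triangles]
    centroids = tri.mean(axis=1)
    tri_areas = mesh.triangle_areas()
    ring_centres = np.array(
        [mesh.vertices[r * n : (r + 1) * n].mean(axis=0) for r in range(n_rings)]
    )
    # band index: triangles are laid out 2n per band then the apex fan
    band = np.minimum(np.arange(len(tri)) // (2 * n), n_rings - 1)
    for t in range(len(tri)):
        b = band[t]
        centre = ring_centres[b]
        theta = np.arctan2(centroids[t, 1] - centre[1], centroids[t, 0] - centre[0])
        areas[b, segment_index(theta, n_segments)] += tri_areas[t]
    return areas / 100.0  # mm^2 -> cm^2
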