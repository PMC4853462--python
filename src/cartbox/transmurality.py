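"""Infarct transmurality and wall thickening per circumferential segment.

Infarct transmurality (IT) is *area based*: per short-axis slice the
myocardium (epicardial minus endocardial contour) and the scar within
it are rasterized at the stack's pixel spacing, the myocardial pixels
are partitioned into 80 angular sectors about the end-diastolic
endocardial centroid, and IT of a sector is 100 x scar area / wall
area.  Wall thickening (WT) is the end-systolic minus end-diastolic
radial wall thickness per sector (mm), measured along rays from the
same centroid.

The five IT classes partition [0, 100]: {0}, (0, 25], (25, 50],
(50, 75], (75, 100] (boundaries belong to the lower class, 0 is its
own class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon as _Poly

from .errors import AnalysisError, GeometryError
from .geometry import N_SEGMENTS, segment_index
from .io import ContourStack
from .mesh import SurfaceMesh

__all__ = [
    "IT_CLASSES",
    "BullseyeGrid",
    "classify_it",
    "classify_it_array",
    "segment_transmurality",
    "wall_thickening",
    "compute_it_bullseye",
    "compute_wt_bullseye",
    "segment_sample_positions",
    "border_zone",
]

IT_CLASSES = ("0%", "0-25%", "25-50%", "50-75%", "75-100%")


@dataclass
class BullseyeGrid:
    """Slices x 80 bullseye of a per-segment scalar (IT % or WT mm)."""

    values: np.ndarray
    slice_z: np.ndarray
    segment_area_cm2: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_SEGMENTS:
            raise AnalysisError(f"bullseye must have {N_SEGMENTS} columns")


def classify_it(it: float) -> str:
    """Map an IT percentage to its transmurality class label.

    0 maps to "0%"; interval upper bounds are inclusive (25 -> "0-25%",
    25.0001 -> "25-50%", 100 -> "75-100%").
    """
    if not np.isfinite(it) or it < 0 or it > 100:
        raise AnalysisError(f"IT must lie in [0, 100], got {it!r}")
    if it == 0:
        return IT_CLASSES[0]
    for hi, label in zip((25.0, 50.0, 75.0, 100.0), IT_CLASSES[1:]):
        if it <= hi:
            return label
    raise AssertionError("unreachable")


def classify_it_array(it: np.ndarray) -> np.ndarray:
    """Vectorized class *index* (0..4) per IT value; NaN -> -1."""
    it = np.asarray(it, dtype=float)
    out = np.full(it.shape, -1, dtype=int)
    ok = np.isfinite(it)
    if np.any((it[ok] < 0) | (it[ok] > 100)):
        raise AnalysisError("IT must lie in [0, 100]")
    vals = it[ok]
    idx = np.searchsorted(np.array([25.0, 50.0, 75.0]), vals, side="left") + 1
    idx[vals == 0] = 0
    out[ok] = idx
    return out


def _pixel_grid(poly: np.ndarray, spacing: float):
    x0, y0 = poly.min(axis=0) - spacing
    x1, y1 = poly.max(axis=0) + spacing
    xs = np.arange(x0 + spacing / 2, x1, spacing)
    ys = np.arange(y0 + spacing / 2, y1, spacing)
    gx, gy = np.meshgrid(xs, ys)
    return gx.ravel(), gy.ravel()


def segment_transmurality(
    stack: ContourStack, slice_index: int, n_segments: int = N_SEGMENTS
) -> np.ndarray:
    """Area-based IT (%) in ``n_segments`` circumferential segments of one slice.

    Returns a vector with NaN for segments containing no myocardial
    pixels.  A scar polygon lying entirely outside the myocardium
    contributes nothing (with a warning).
    """
    s = stack.slices[slice_index]
    spacing = stack.pixel_spacing_mm
    if spacing <= 0:
        raise GeometryError("pixel_spacing must be positive")
    gx, gy = _pixel_grid(s.epi_ed, spacing)
    epi = _Poly(s.epi_ed)
    endo = _Poly(s.endo_ed)
    myo = contains_xy(epi, gx, gy) & ~contains_xy(endo, gx, gy)
    scar = np.zeros_like(myo)
    for j, sp in enumerate(s.scar):
        hit = contains_xy(_Poly(sp), gx, gy)
        if not np.any(hit & myo):
            warnings.warn(
                f"slice {slice_index}: scar polygon {j} lies outside the myocardium",
                stacklevel=2,
            )
        scar |= hit
    scar &= myo

    centre = np.asarray(endo.centroid.coords[0])
    theta = np.arctan2(gy - centre[1], gx - centre[0])
    seg = segment_index(theta, n_segments)
    myo_counts = np.bincount(seg[myo], minlength=n_segments).astype(float)
    scar_counts = np.bincount(seg[scar], minlength=n_segments).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        it = 100.0 * scar_counts / myo_counts
    it[myo_counts == 0] = np.nan
    return it


def _ray_radii(poly: np.ndarray, centre: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Distance from ``centre`` to the polygon boundary along each angle.

    Takes the nearest positive crossing; NaN when a ray misses.
    """
    a = poly - centre
    b = np.roll(poly, -1, axis=0) - centre
    d = np.column_stack([np.cos(angles), np.sin(angles)])  # (k, 2)
    e = b - a  # (m, 2)
    # solve a_m + u e_m = t d_k : 2x2 per (k, m)
    det = d[:, None, 0] * (-e[None, :, 1]) - d[:, None, 1] * (-e[None, :, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a[None, :, 0] * (-e[None, :, 1]) - a[None, :, 1] * (-e[None, :, 0])) / det
        u = (d[:, None, 0] * a[None, :, 1] - d[:, None, 1] * a[None, :, 0]) / det
    valid = (u >= 0.0) & (u < 1.0) & (t > 0.0) & np.isfinite(t)
    t = np.where(valid, t, np.inf)
    r = t.min(axis=1)
    r[~np.isfinite(r)] = np.nan
    return r


def wall_thickening(
    stack: ContourStack,
    slice_index: int,
    n_segments: int = N_SEGMENTS,
    rays_per_segment: int = 3,
) -> np.ndarray:
    """Wall thickening (mm) per segment: ES minus ED radial wall thickness.

    Thickness is the mean epicardial-minus-endocardial radius over rays
    cast from the ED endocardial centroid through each sector; segments
    where any ray misses a contour are NaN.  Negative values (systolic
    thinning) are possible over transmural scar.
    """
    s = stack.slices[slice_index]
    centre = np.asarray(_Poly(s.endo_ed).centroid.coords[0])
    width = 2 * np.pi / n_segments
    # sector k covers mathematical angle (-(k+1)w, -kw]; sample its interior
    offsets = (np.arange(rays_per_segment) + 0.5) / rays_per_segment
    angles = (-(np.arange(n_segments)[:, None] + offsets[None, :]) * width).ravel()

    def thickness(endo, epi):
        r_endo = _ray_radii(endo, centre, angles)
        r_epi = _ray_radii(epi, centre, angles)
        return (r_epi - r_endo).reshape(n_segments, rays_per_segment)

    th_ed = thickness(s.endo_ed, s.epi_ed)
    th_es = thickness(s.endo_es, s.epi_es)
    wt = np.mean(th_es - th_ed, axis=1)
    wt[np.any(~np.isfinite(th_ed) | ~np.isfinite(th_es), axis=1)] = np.nan
    return wt


def compute_it_bullseye(stack: ContourStack) -> BullseyeGrid:
    values = np.vstack([segment_transmurality(stack, i) for i in range(stack.n_slices)])
    return BullseyeGrid(values=values, slice_z=stack.slice_z)


def compute_wt_bullseye(stack: ContourStack) -> BullseyeGrid:
    values = np.vstack([wall_thickening(stack, i) for i in range(stack.n_slices)])
    return BullseyeGrid(values=values, slice_z=stack.slice_z)


def segment_sample_positions(stack: ContourStack, n_segments: int = N_SEGMENTS) -> np.ndarray:
    """3D endocardial position of each bullseye cell's sector centre.

    Used to project per-segment bullseye values (IT, WT) onto the mesh
    as a scattered field: one sample per (slice, segment) at the ED
    endocardial boundary, z from the slice position.
    """
    width = 2 * np.pi / n_segments
    angles = -(np.arange(n_segments) + 0.5) * width
    out = np.empty((stack.n_slices, n_segments, 3))
    for i, s in enumerate(stack.slices):
        centre = np.asarray(_Poly(s.endo_ed).centroid.coords[0])
        r = _ray_radii(s.endo_ed, centre, angles)
        out[i, :, 0] = centre[0] + r * np.cos(angles)
        out[i, :, 1] = centre[1] + r * np.sin(angles)
        out[i, :, 2] = s.z_mm
    return out.reshape(-1, 3)


def border_zone(
    mesh: SurfaceMesh, lo: float = 0.0, hi: float = 75.0, adjacent_to_core: bool = False
) -> np.ndarray:
    """Vertex mask of the infarct border zone.

    The border zone is declared as the infarcted but non-transmural
    rim: vertices with ``lo < it <= hi``.  With ``adjacent_to_core``
    the mask is restricted to vertices edge-adjacent to the transmural
    core (``it > hi``).
    """
    if not 0 <= lo < hi <= 100:
        raise AnalysisError("need 0 <= lo < hi <= 100")
    if "it" not in mesh.vertex_channels:
        raise AnalysisError("mesh has no 'it' channel")
    it = mesh.vertex_channels["it"]
    mask = (it > lo) & (it <= hi)
    if adjacent_to_core and np.any(mask):
        core = it > hi
        near_core = np.zeros_like(mask)
        for a, b in mesh.edges():
            if core[a]:
                near_core[b] = True
            if core[b]:
                near_core[a] = True
        mask &= near_core
    return mask
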