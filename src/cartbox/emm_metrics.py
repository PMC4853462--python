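"""Derived electromechanical quantities: linear local shortening and
point-density summaries per infarct-transmurality class.

Linear local shortening (LLS) of an index point is the weighted mean
percent change of its distances to all other mapped points between end
diastole and maximal systole: positive values mean shortening
(contraction).  Neighbors are emphasized by a distance window on the
end-diastolic separation: full weight between 8 and 15 mm, ramping
linearly to zero at 4 and 25 mm.  The window is isolated in
:func:`lls_weight` so alternative weightings can be swapped in; the
identities used in testing (uniform scaling by s gives LLS =
100 (1 - s) everywhere) hold for any non-negative weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import AnalysisError
from .io import EMMMap
from .mesh import SurfaceMesh
from .transmurality import IT_CLASSES, BullseyeGrid, classify_it_array

__all__ = ["lls_weight", "compute_lls", "DensityReport", "point_density"]


def lls_weight(d_mm: np.ndarray, band_mm: tuple = (8.0, 15.0)) -> np.ndarray:
    """Tent weighting on end-diastolic neighbor distance (mm).

    1 inside ``band_mm``, with linear ramps reaching 0 at half the
    inner edge and 10 mm past the outer edge (4 and 25 mm for the
    default 8-15 mm band); zero beyond.
    """
    lo, hi = band_mm
    ramp_lo, ramp_hi = lo / 2.0, hi + 10.0
    d = np.asarray(d_mm, dtype=float)
    w = np.zeros_like(d)
    up = (d > ramp_lo) & (d < lo)
    w[up] = (d[up] - ramp_lo) / (lo - ramp_lo)
    w[(d >= lo) & (d <= hi)] = 1.0
    down = (d > hi) & (d < ramp_hi)
    w[down] = (ramp_hi - d[down]) / (ramp_hi - hi)
    return w


def compute_lls(
    ed_positions: np.ndarray,
    es_positions: np.ndarray,
    band_mm: tuple = (8.0, 15.0),
) -> np.ndarray:
    """Per-point linear local shortening (%) from ED and ES positions.

    For index point i::

        LLS_i = 100 * sum_j w_ij (d_ij^ED - d_ij^ES) / sum_j w_ij d_ij^ED

    with j over all other points and w the distance weighting on the ED
    separation.  Points whose weights are all zero get NaN.
    """
    ed = np.asarray(ed_positions, dtype=float)
    es = np.asarray(es_positions, dtype=float)
    if ed.shape != es.shape or ed.ndim != 2 or ed.shape[1] != 3:
        raise AnalysisError("ED and ES positions must both be (n, 3)")
    n = len(ed)
    if n < 2:
        raise AnalysisError("need at least 2 points for LLS")
    d_ed = squareform(pdist(ed))
    d_es = squareform(pdist(es))
    w = lls_weight(d_ed, band_mm)
    np.fill_diagonal(w, 0.0)
    denom = np.sum(w * d_ed, axis=1)
    num = np.sum(w * (d_ed - d_es), axis=1)
    out = np.full(n, np.nan)
    ok = denom > 0
    out[ok] = 100.0 * num[ok] / denom[ok]
    return out


@dataclass
class DensityReport:
    """EMM point counts, endocardial areas and densities per IT class."""

    classes: tuple
    n_points: np.ndarray
    area_cm2: np.ndarray
    density_pts_per_cm2: np.ndarray

    @property
    def total_points(self) -> int:
        return int(self.n_points.sum())

    def as_dict(self) -> dict:
        return {
            label: {
                "n_points": int(self.n_points[i]),
                "area_cm2": float(self.area_cm2[i]),
                "density_pts_per_cm2": float(self.density_pts_per_cm2[i]),
            }
            for i, label in enumerate(self.classes)
        }


def point_density(emm: EMMMap, mesh: SurfaceMesh, grid: BullseyeGrid) -> DensityReport:
    """Point density (points/cm^2) in each infarct-transmurality class.

    Each included point takes the IT class of its closest mesh vertex
    (``it`` channel required); the class area is the summed endocardial
    segment area over bullseye cells of that class.  Registration and
    analysis filtering are assumed to have been applied.
    """
    if "it" not in mesh.vertex_channels:
        raise AnalysisError("mesh has no 'it' channel")
    if grid.segment_area_cm2 is None:
        raise AnalysisError("bullseye grid lacks segment areas")
    pts = emm.positions[emm.included]
    if len(pts) == 0:
        raise AnalysisError("no included points")
    nearest = cKDTree(mesh.vertices).query(pts)[1]
    point_cls = classify_it_array(mesh.vertex_channels["it"][nearest])

    cell_cls = classify_it_array(grid.values)
    areas = np.zeros(len(IT_CLASSES))
    for c in range(len(IT_CLASSES)):
        areas[c] = np.nansum(np.where(cell_cls == c, grid.segment_area_cm2, 0.0))
    counts = np.bincount(point_cls[point_cls >= 0], minlength=len(IT_CLASSES)).astype(float)
    if np.any((areas == 0) & (counts > 0)):
        raise AnalysisError("points assigned to an IT class with zero area")
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(areas > 0, counts / areas, 0.0)
    return DensityReport(
        classes=IT_CLASSES,
        n_points=counts.astype(int),
        area_cm2=areas,
        density_pts_per_cm2=dens,
    )
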