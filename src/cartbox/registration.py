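"""Rigid registration of EMM point clouds onto the endocardial mesh.

The registration chain mirrors the catheter-lab workflow:

1. a constant *standard axes* rotation maps the mapping system's frame
   onto the MRI frame (a fixed convention, no data dependence);
2. *apex alignment* translates the EMM apex onto the mesh apex and
   tilts the cloud's principal long axis onto the mesh long axis;
3. a *rotation-constrained ICP* refines the fit, with cumulative Euler
   rotations about the apex clamped to +/-(10, 20, 20) degrees in the
   sagittal, coronal and transverse planes;
4. optional *manual adjustment* composes a bounded 6-DOF tweak
   (single rotations above 5 degrees are refused).

Rotations are Euler angles in degrees about the fixed x (sagittal),
y (coronal) and z (transverse) axes, applied in that order about a
stated pivot; the registration pivot is always the mesh apex.  The
registration error is the mean +/- SD of the closest distance between
the (included) EMM points and the mesh surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError, RegistrationError, RotationBoundError
from .io import EMMMap
from .mesh import SurfaceMesh

__all__ = [
    "RigidTransform",
    "ErrorStats",
    "AXIS_CONVENTIONS",
    "standard_axes_transform",
    "apex_align",
    "roll_align",
    "constrained_icp",
    "manual_adjust",
    "refine_registration",
    "registration_error",
    "filter_points",
    "chain",
]

_AXES = ("sagittal", "coronal", "transverse")


@dataclass(frozen=True)
class RigidTransform:
    """Rigid transform  x -> R (x - pivot) + pivot + translation.

    ``euler_deg`` are (sagittal, coronal, transverse) rotations in
    degrees about the fixed x, y, z axes applied in that order.
    """

    euler_deg: tuple = (0.0, 0.0, 0.0)
    translation: tuple = (0.0, 0.0, 0.0)
    pivot: tuple = (0.0, 0.0, 0.0)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.euler_deg, degrees=True).as_matrix()

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 form."""
        rot = self.rotation_matrix
        piv = np.asarray(self.pivot, dtype=float)
        m = np.eye(4)
        m[:3, :3] = rot
        m[:3, 3] = piv + np.asarray(self.translation) - rot @ piv
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray, pivot=(0.0, 0.0, 0.0)) -> "RigidTransform":
        rot = m[:3, :3]
        piv = np.asarray(pivot, dtype=float)
        euler = Rotation.from_matrix(rot).as_euler("xyz", degrees=True)
        translation = m[:3, 3] + rot @ piv - piv
        return cls(tuple(euler), tuple(translation), tuple(piv))

    @classmethod
    def from_rotation_matrix(cls, rot, translation=(0, 0, 0), pivot=(0, 0, 0)):
        euler = Rotation.from_matrix(rot).as_euler("xyz", degrees=True)
        return cls(tuple(euler), tuple(np.asarray(translation, float)), tuple(pivot))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        piv = np.asarray(self.pivot, dtype=float)
        return (pts - piv) @ self.rotation_matrix.T + piv + np.asarray(self.translation)

    def apply_to_emm(self, emm: EMMMap) -> EMMMap:
        out = emm.copy()
        out.positions = self.apply(emm.positions)
        if out.trajectories is not None:
            shape = out.trajectories.shape
            out.trajectories = self.apply(out.trajectories.reshape(-1, 3)).reshape(shape)
        return out

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix), self.pivot)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then self."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix, self.pivot)


def chain(*transforms: RigidTransform, pivot=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Compose transforms applied left-to-right into one (given pivot)."""
    m = np.eye(4)
    for t in transforms:
        m = t.matrix @ m
    return RigidTransform.from_matrix(m, pivot)


@dataclass
class ErrorStats:
    """Registration error summary: closest point-to-surface distances (mm)."""

    per_point_mm: np.ndarray
    n_excluded: int = 0

    @property
    def n_points(self) -> int:
        return len(self.per_point_mm)

    @property
    def mean_mm(self) -> float:
        return float(np.mean(self.per_point_mm))

    @property
    def sd_mm(self) -> float:
        if self.n_points < 2:
            return 0.0
        return float(np.std(self.per_point_mm, ddof=1))


#: Named frame conventions for the standard axes rotation.  Each entry is
#: the 3x3 rotation applied to mapping-system coordinates to express them
#: in the MRI frame.  The catheter system's export frame is configured
#: here once per site; "identity" is appropriate when both datasets are
#: already in the package's patient-like frame.
AXIS_CONVENTIONS = {
    "identity": np.eye(3),
    # y and z swapped with a sign flip (y_map -> z_mri, z_map -> -y_mri)
    "swap_yz": np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]]),
    # half-turn about the long axis (x and y negated)
    "flip_xy": np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]]),
}


def standard_axes_transform(convention: str = "identity") -> RigidTransform:
    """Constant frame-swap rotation between mapping and MRI frames."""
    if convention not in AXIS_CONVENTIONS:
        raise ConfigError(
            f"unknown axis convention '{convention}'; known: {sorted(AXIS_CONVENTIONS)}"
        )
    return RigidTransform.from_rotation_matrix(AXIS_CONVENTIONS[convention])


def _circle_centre(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) circle fit: centre and radius of 2D points."""
    a = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = np.einsum("ij,ij->i", xy, xy)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy, c = sol
    r = float(np.sqrt(max(c + cx**2 + cy**2, 0.0)))
    return np.array([cx, cy]), r


def _refine_axis(points: np.ndarray, axis: np.ndarray) -> tuple[np.ndarray, float]:
    """Refine a long-axis guess via band-wise circle centres.

    Slices the cloud into bands along the axis, fits a circle centre
    to each band's cross-section and refits the axis as the line
    through the centres; returns (axis, score) where the score is the
    mean circle-fit residual (lower = more circular cross-sections,
    i.e. a more plausible long axis).  Circle centres are insensitive
    to the inhomogeneous angular point density of mapping
    acquisitions, which badly biases raw PCA.
    """
    score = np.inf
    for _ in range(4):
        t = points @ axis
        edges = np.linspace(t.min(), t.max(), 7)
        centres, radii, weights, resids = [], [], [], []
        for k in range(len(edges) - 1):
            sel = (t >= edges[k]) & (t <= edges[k + 1])
            if sel.sum() < 8:
                continue
            e1 = np.eye(3)[np.argmin(np.abs(axis))]
            e1 = e1 - axis * (e1 @ axis)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis, e1)
            xy = np.column_stack([points[sel] @ e1, points[sel] @ e2])
            c2d, r = _circle_centre(xy)
            resids.append(np.mean(np.abs(np.linalg.norm(xy - c2d, axis=1) - r)))
            centres.append(c2d[0] * e1 + c2d[1] * e2 + np.mean(t[sel]) * axis)
            radii.append(r)
            weights.append(sel.sum())
        if len(centres) < 3:
            break
        score = float(np.mean(resids))
        centres = np.asarray(centres)
        w = np.asarray(weights, dtype=float)
        mean_c = np.average(centres, axis=0, weights=w)
        _, _, vt = np.linalg.svd((centres - mean_c) * np.sqrt(w)[:, None], full_matrices=False)
        new_axis = vt[0]
        if new_axis @ axis < 0:
            new_axis = -new_axis
        if np.allclose(new_axis, axis, atol=1e-6):
            axis = new_axis
            break
        axis = new_axis
    return axis, score


def _principal_axis_apex(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Estimate (apex position, unit long axis apex->base) of an EMM cloud.

    Each principal direction of the cloud is refined with
    :func:`_refine_axis`; the candidate whose band cross-sections are
    most circular wins.  The apex estimate is the most extreme point
    along the final axis on the closed (small-radius) end.
    """
    centred = points - points.mean(axis=0)
    _, _, vt0 = np.linalg.svd(centred, full_matrices=False)
    axis, best_score = None, np.inf
    for guess in vt0:
        cand, score = _refine_axis(points, guess)
        if score < best_score:
            axis, best_score = cand, score
    # orient apex->base by closedness: the apex end of the cloud has
    # points near the axis, the basal end is an open rim (no points at
    # small radius), which is robust even for barrel-like ventricles
    proj = points @ axis
    axis_point = points.mean(axis=0)
    radial = np.linalg.norm(
        (points - axis_point) - np.outer(proj - axis_point @ axis, axis), axis=1
    )
    k = max(3, len(points) // 8)
    order = np.argsort(proj)
    r_min_lo = radial[order[:k]].min()
    r_min_hi = radial[order[-k:]].min()
    if r_min_hi < r_min_lo:
        axis = -axis
        proj = -proj
    # most extreme point along the axis; near-ties (within 0.5 mm) are
    # broken toward the axis, the morphological apex
    band = proj <= proj.min() + 0.5
    cand = np.nonzero(band)[0]
    apex_idx = int(cand[np.argmin(radial[cand])])
    return points[apex_idx], axis


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    w = np.cross(u, v)
    s = np.linalg.norm(w)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate half-turn about any perpendicular axis
        perp = np.eye(3)[np.argmin(np.abs(u))]
        perp = perp - u * np.dot(perp, u)
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    wx = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + wx + wx @ wx * ((1 - c) / s**2)


def _translation_polish(points: np.ndarray, mesh: SurfaceMesh, max_iter: int = 10) -> np.ndarray:
    """Translation-only fit: iteratively shift the cloud by the mean
    offset to the closest surface feet.  Robust regardless of any
    residual rotation and unaffected by surface symmetry."""
    total = np.zeros(3)
    moved = points.copy()
    for _ in range(max_iter):
        _, foot, _ = mesh.closest(moved)
        shift = (foot - moved).mean(axis=0)
        if np.linalg.norm(shift) < 0.01:
            break
        moved += shift
        total += shift
    return total


def roll_align(emm: EMMMap, mesh: SurfaceMesh, search_deg: float = 20.0) -> RigidTransform:
    """Best rotation about the mesh long axis by 1-D search.

    Minimizes the mean closest point-to-surface distance over roll
    angles in ``+/-search_deg`` (coarse 2-degree grid, then 0.25-degree
    refinement).  Roll is invisible to the point-to-foot ICP update on
    near-rotationally-symmetric ventricles (the update has no
    first-order component along the symmetry direction), so it must be
    fixed by direct search before ICP.  On a perfectly circular
    cross-section the objective is flat and the result harmless.
    """
    pts = emm.positions[emm.included]
    if len(pts) == 0:
        raise RegistrationError("no included EMM points")
    axis = mesh.long_axis
    pivot = mesh.apex

    def at(angle_deg: float) -> RigidTransform:
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        m = np.eye(4)
        m[:3, :3] = rot
        m[:3, 3] = pivot - rot @ pivot
        return RigidTransform.from_matrix(m, pivot)

    def cost(angle_deg: float) -> float:
        return float(np.mean(mesh.closest(at(angle_deg).apply(pts))[0]))

    step = max(2.5, search_deg / 36.0)
    coarse = np.arange(-search_deg, search_deg + 1e-9, step)
    best = coarse[int(np.argmin([cost(a) for a in coarse]))]
    fine = best + np.arange(-step, step + 1e-9, step / 6.0)
    best = fine[int(np.argmin([cost(a) for a in fine]))]
    return at(float(best))


def apex_align(
    emm: EMMMap, mesh: SurfaceMesh, emm_apex="auto", roll: str | float = "auto"
) -> RigidTransform:
    """Rigid initialization: map the EMM apex onto the mesh apex and the
    EMM principal long axis onto the mesh long axis.

    ``emm_apex`` is a point id or "auto" (estimate from the cloud's
    shape).  With ``roll="auto"`` the residual rotation about the long
    axis is resolved by :func:`roll_align`; a numeric ``roll`` fixes it
    explicitly (0 leaves it untouched).  The pivot of the returned
    transform is the mesh apex.
    """
    pts = emm.positions[emm.included]
    if len(pts) < 10:
        raise RegistrationError("need at least 10 included EMM points for apex alignment")
    if emm_apex == "auto":
        apex_pos, axis_up = _principal_axis_apex(pts)
    else:
        sel = np.nonzero(emm.ids == emm_apex)[0]
        if len(sel) == 0:
            raise RegistrationError(f"no EMM point with id {emm_apex}")
        apex_pos = emm.positions[sel[0]]
        _, axis_up = _principal_axis_apex(pts)
    mesh_apex = mesh.apex
    rot = _rotation_between(axis_up, mesh.long_axis)
    t0 = mesh_apex - apex_pos  # apex -> apex translation, applied before rotation
    base = RigidTransform.from_rotation_matrix(rot, rot @ t0, pivot=mesh_apex)
    if roll == "auto":
        # the apex estimate is one sampled point, so the translation is
        # only good to the local point spacing; polish it before (and
        # after) resolving the roll, which is sensitive to offsets
        shift = _translation_polish(base.apply(pts), mesh)
        base = RigidTransform(translation=tuple(shift)).compose(base)
        t_roll = roll_align(base.apply_to_emm(emm), mesh, search_deg=30.0)
        base = t_roll.compose(base)
        shift = _translation_polish(base.apply(pts), mesh)
        return RigidTransform(translation=tuple(shift)).compose(base)
    if roll:
        axis = mesh.long_axis
        rot_r = Rotation.from_rotvec(np.deg2rad(float(roll)) * axis).as_matrix()
        extra = RigidTransform.from_rotation_matrix(rot_r, pivot=mesh_apex)
        return extra.compose(base)
    return base


def _solve_rigid(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares rigid transform (4x4) mapping src onto dst (Kabsch/SVD)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    m = np.eye(4)
    m[:3, :3] = rot
    m[:3, 3] = cd - rot @ cs
    return m


def constrained_icp(
    emm: EMMMap,
    mesh: SurfaceMesh,
    limits_deg: tuple = (10.0, 20.0, 20.0),
    tol_mm: float = 0.01,
    max_iter: int = 100,
) -> tuple[RigidTransform, list]:
    """Iterative closest point with rotations clamped about the apex.

    Expects a cloud that is already standard-axes and apex aligned.
    Each iteration matches every included point to its closest surface
    foot point, solves the least-squares rigid update by SVD, and
    clamps the *cumulative* Euler angles (relative to the ICP start)
    to ``+/-limits_deg`` componentwise.  Iteration stops when the mean
    closest-distance improvement falls below ``tol_mm`` or after
    ``max_iter`` iterations; updates that would increase the mean error
    are rejected.  Returns the cumulative transform (pivot = mesh apex)
    and the trace of accepted :class:`ErrorStats`, whose mean is
    non-increasing.
    """
    if not np.any(emm.included):
        raise RegistrationError("no included EMM points")
    limits = np.asarray(limits_deg, dtype=float)
    pts0 = emm.positions[emm.included]
    pivot = mesh.apex
    t_cum = RigidTransform(pivot=tuple(pivot))

    d, _, _ = mesh.closest(pts0)
    trace = [ErrorStats(per_point_mm=d, n_excluded=emm.n_points - emm.n_included)]
    prev_mean = trace[0].mean_mm

    for it in range(max_iter):
        cur = t_cum.apply(pts0)
        _, foot, _ = mesh.closest(cur)
        m_inc = _solve_rigid(cur, foot)
        if not np.all(np.isfinite(m_inc)):
            raise RegistrationError(f"non-finite ICP update at iteration {it}")
        cand = RigidTransform.from_matrix(m_inc @ t_cum.matrix, pivot)
        clamped = np.clip(np.asarray(cand.euler_deg), -limits, limits)
        cand = RigidTransform(tuple(clamped), cand.translation, cand.pivot)

        d_new, _, _ = mesh.closest(cand.apply(pts0))
        new_mean = float(np.mean(d_new))
        improvement = prev_mean - new_mean
        if new_mean <= prev_mean:
            t_cum = cand
            trace.append(ErrorStats(per_point_mm=d_new, n_excluded=trace[0].n_excluded))
            prev_mean = new_mean
        if improvement < tol_mm:
            break
    return t_cum, trace


def manual_adjust(
    t: RigidTransform,
    delta,
    rot_bound_deg: float = 5.0,
    enforce_bound: bool = True,
) -> RigidTransform:
    """Compose a bounded manual 6-DOF tweak onto an existing transform.

    ``delta`` is (sagittal deg, coronal deg, transverse deg, tx, ty, tz);
    any single rotation component exceeding ``rot_bound_deg`` is refused
    unless the bound is explicitly disabled.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (6,):
        raise ConfigError("delta must be a 6-vector (3 rotations deg, 3 translations mm)")
    if enforce_bound:
        for i, name in enumerate(_AXES):
            if abs(delta[i]) > rot_bound_deg:
                raise RotationBoundError(
                    f"{name} rotation exceeds {rot_bound_deg:g} degrees"
                )
    d = RigidTransform(tuple(delta[:3]), tuple(delta[3:]), t.pivot)
    return d.compose(t)


def refine_registration(
    emm: EMMMap,
    mesh: SurfaceMesh,
    rot_bound_deg: float = 5.0,
    trans_bound_mm: float = 5.0,
) -> RigidTransform:
    """Bounded 6-DOF polish minimizing the mean closest distance.

    Automated counterpart of the interactive fine adjustment that
    follows ICP: a derivative-free (Powell) search over the three
    rotations about the apex (each bounded to ``rot_bound_deg``, the
    same 5-degree cap enforced for manual tweaks) and the three
    translations.  Point-to-foot ICP leaves a shallow tilt/translation
    valley on smooth ventricles because its update has little
    first-order sensitivity to surface-tangential motion; directly
    minimizing the registration error removes that residual.
    """
    from scipy.optimize import minimize

    if not np.any(emm.included):
        raise RegistrationError("no included EMM points")
    pts = emm.positions[emm.included]
    pivot = mesh.apex

    def cost(x):
        t = RigidTransform(tuple(x[:3]), tuple(x[3:]), tuple(pivot))
        return float(np.mean(mesh.closest(t.apply(pts))[0]))

    bounds = [(-rot_bound_deg, rot_bound_deg)] * 3 + [(-trans_bound_mm, trans_bound_mm)] * 3
    res = minimize(
        cost,
        np.zeros(6),
        method="Powell",
        bounds=bounds,
        options={"xtol": 5e-3, "ftol": 1e-6, "maxfev": 250},
    )
    return RigidTransform(tuple(res.x[:3]), tuple(res.x[3:]), tuple(pivot))


def registration_error(emm: EMMMap, mesh: SurfaceMesh) -> ErrorStats:
    """Mean/SD of closest EMM-point-to-surface distance over included points."""
    if not np.any(emm.included):
        raise RegistrationError("no included EMM points")
    d, _, _ = mesh.closest(emm.positions[emm.included])
    return ErrorStats(per_point_mm=d, n_excluded=emm.n_points - emm.n_included)


def filter_points(
    emm: EMMMap,
    mesh: SurfaceMesh,
    exclude_basal_slices: int = 0,
    contact_tol_mm: float = 5.0,
) -> EMMMap:
    """Return a copy with out-of-ventricle (and optionally basal) points excluded.

    A point is excluded when it lies outside the basally-capped cavity
    *and* farther than ``contact_tol_mm`` from the surface (ordinary
    wall-contact points sit slightly outside the endocardial mesh).
    With ``exclude_basal_slices > 0`` (analysis mode) points whose
    closest mesh vertex lies in the most basal slices are excluded too.
    """
    out = emm.copy()
    pts = out.positions
    inside = mesh.contains(pts)
    dist, _, _ = mesh.closest(pts)
    out.included &= inside | (dist <= contact_tol_mm)
    if exclude_basal_slices > 0:
        from scipy.spatial import cKDTree

        nearest_vertex = cKDTree(mesh.vertices).query(pts)[1]
        basal = mesh.slice_of_vertex[nearest_vertex] < exclude_basal_slices
        out.included &= ~basal
    return out
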