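"""Ground-truthed synthetic infarcted-LV datasets.

The phantom is a truncated-ellipsoid left ventricle: the endocardium
is an ellipsoid with semi-axes (a, b, c) mm truncated at the base, the
epicardium a concentric ellipsoid one wall-thickness larger.  A single
infarct is a spatially smooth transmurality field IT(theta, z) in
[0, 100] %, peaking at a configurable circumferential angle and
decaying smoothly in angle and along the long axis; per slice the scar
contour is the radial band of the wall whose in-plane area fraction
equals the local IT.  End-systolic contours thicken the wall in
proportion to local viability (1 - IT/100), so wall thickening
recovers the coupling by construction.

EMM points are sampled on the endocardial surface with configurable
oversampling of the dense-scar (IT > 75 %) territory — mapping
catheters dwell in and around the infarct — then jittered with contact
noise.  Voltages follow a linear IT link with Gaussian noise (defaults
bracket clinically used cutoffs so threshold-recovery simulations are
meaningful; they are simulation knobs, not physiology).  LLS is
computed from the simulated ED/ES trajectories with the package's own
definition.  A known rigid perturbation can then be applied to create
the mis-registration the registration chain must undo.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .emm_metrics import compute_lls
from .errors import ConfigError
from .geometry import N_SEGMENTS
from .io import ContourStack, EMMMap, SliceContours
from .mesh import SurfaceMesh, build_endocardial_mesh
from .registration import RigidTransform
from .transmurality import BullseyeGrid

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "sample_emm", "perturb_rigid"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic infarcted LV (lengths mm, angles deg)."""

    # geometry
    endo_semi_axes: tuple = (25.0, 25.0, 60.0)
    wall_mm: float = 10.0
    n_slices: int = 20
    base_truncation_fraction: float = 0.0  # base plane at z = c * fraction
    contour_points: int = 96
    # infarct
    infarct_center_deg: float = 0.0
    infarct_width_deg: float = 120.0
    infarct_extent_fraction: float = 0.6  # apex-base extent of the scar
    peak_it: float = 95.0
    # EMM sampling
    n_points: int = 150
    contact_noise_mm: float = 1.0
    uv_healthy_mv: float = 12.0
    uv_scar_mv: float = 4.0
    bv_healthy_mv: float = 3.0
    bv_scar_mv: float = 0.5
    uv_noise_mv: float = 1.5
    bv_noise_mv: float = 0.4
    oversample_factor: float = 2.0  # density boost where IT > 75 %
    # motion
    contraction: float = 0.15  # healthy fractional radial contraction at ES
    it_coupling: float = 1.0  # 1: scar does not contract at all
    wt_healthy_mm: float = 6.0  # healthy-wall thickening (mm)

    def __post_init__(self):
        a, b, c = self.endo_semi_axes
        if min(a, b, c, self.wall_mm) <= 0 or self.n_slices < 3:
            raise ConfigError("phantom dimensions must be positive, n_slices >= 3")
        if not 0 <= self.peak_it <= 100:
            raise ConfigError("peak IT must lie in [0, 100]")
        if not 0 < self.infarct_extent_fraction <= 1.0:
            raise ConfigError("infarct extent must lie in (0, 1] of the apex-base span")
        if not 0 <= self.base_truncation_fraction < 1.0:
            raise ConfigError("base truncation fraction must lie in [0, 1)")


def _ellipse_radius(a: float, b: float, theta: np.ndarray) -> np.ndarray:
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def _wrap_angle(x: np.ndarray) -> np.ndarray:
    return (x + np.pi) % (2 * np.pi) - np.pi


@dataclass
class Phantom:
    """Generated phantom with its analytic ground truth."""

    spec: PhantomSpec
    stack: ContourStack
    mesh: SurfaceMesh
    it_bullseye: BullseyeGrid

    def it_at(self, theta: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Analytic IT field (%) at circumferential angle(s)/height(s)."""
        s = self.spec
        a, b, c = s.endo_semi_axes
        z_base = c * s.base_truncation_fraction
        # apex-base coordinate u in [0 (apex), 1 (base)]
        u = np.clip((np.asarray(z) + c) / (z_base + c), 0.0, 1.0)
        e = s.infarct_extent_fraction
        ramp = np.clip((u - 0.7 * e) / (0.3 * e), 0.0, 1.0)
        f_long = np.cos(0.5 * np.pi * ramp) ** 2
        half_w = np.deg2rad(s.infarct_width_deg) / 2.0
        d = np.abs(_wrap_angle(np.asarray(theta) - np.deg2rad(s.infarct_center_deg)))
        f_ang = np.where(d < half_w, np.cos(0.5 * np.pi * d / half_w) ** 2, 0.0)
        return s.peak_it * f_ang * f_long

    def it_at_points(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return self.it_at(np.arctan2(p[:, 1], p[:, 0]), p[:, 2])


def _slice_levels(spec: PhantomSpec) -> np.ndarray:
    a, b, c = spec.endo_semi_axes
    z_base = c * spec.base_truncation_fraction
    h = (z_base + c) / spec.n_slices
    return z_base - h * np.arange(spec.n_slices)


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Build contours, mesh and analytic IT bullseye for a phantom spec.

    Slices run base -> apex with the most apical slice one slice
    spacing above the true apex (its ring closes the mesh via the apex
    fan).  The returned bullseye is the analytic per-segment area
    ratio, the reference the rasterized measurement should reproduce.
    """
    a, b, c = spec.endo_semi_axes
    w = spec.wall_mm
    theta = np.linspace(0, 2 * np.pi, spec.contour_points, endpoint=False)
    levels = _slice_levels(spec)

    ph = Phantom(spec=spec, stack=None, mesh=None, it_bullseye=None)  # field init below

    slices = []
    for z in levels:
        frac = np.sqrt(max(1.0 - (z / c) ** 2, 1e-6))
        frac_epi = np.sqrt(max(1.0 - (z / (c + w)) ** 2, 0.0))
        r_endo = _ellipse_radius(a * frac, b * frac, theta)
        r_epi = _ellipse_radius((a + w) * frac_epi, (b + w) * frac_epi, theta)
        endo = np.column_stack([r_endo * np.cos(theta), r_endo * np.sin(theta)])
        epi = np.column_stack([r_epi * np.cos(theta), r_epi * np.sin(theta)])

        it = ph.it_at(theta, z)
        scar_polys = []
        sel = it > 0.5
        if sel.sum() >= 3:
            # single contiguous lobe in angle: order support around the centre
            d = _wrap_angle(theta - np.deg2rad(spec.infarct_center_deg))
            order = np.argsort(d[sel])
            th_s = theta[sel][order]
            r_i = r_endo[sel][order]
            r_o = r_epi[sel][order]
            r_scar = np.sqrt(r_i**2 + (it[sel][order] / 100.0) * (r_o**2 - r_i**2))
            outer = np.column_stack([r_scar * np.cos(th_s), r_scar * np.sin(th_s)])
            inner = np.column_stack([r_i * np.cos(th_s), r_i * np.sin(th_s)])[::-1]
            scar_polys.append(np.vstack([outer, inner]))

        # ES: endocardium moves inward by the viability-coupled thickening
        delta = spec.wt_healthy_mm * (1.0 - spec.it_coupling * it / 100.0)
        r_endo_es = np.maximum(r_endo - delta, 0.2 * r_endo)
        endo_es = np.column_stack([r_endo_es * np.cos(theta), r_endo_es * np.sin(theta)])

        slices.append(
            SliceContours(
                z_mm=float(z),
                endo_ed=endo,
                epi_ed=epi,
                endo_es=endo_es,
                epi_es=epi.copy(),
                scar=scar_polys,
            )
        )

    stack = ContourStack(slices=slices, pixel_spacing_mm=0.25)
    stack.validate()
    mesh = build_endocardial_mesh(stack, points_per_ring=N_SEGMENTS)

    # analytic per-segment IT: area-ratio quadrature over each sector
    sub = 24
    width = 2 * np.pi / N_SEGMENTS
    gt = np.empty((spec.n_slices, N_SEGMENTS))
    for i, z in enumerate(levels):
        frac = np.sqrt(max(1.0 - (z / c) ** 2, 1e-6))
        frac_epi = np.sqrt(max(1.0 - (z / (c + w)) ** 2, 0.0))
        for k in range(N_SEGMENTS):
            th = -(k * width + (np.arange(sub) + 0.5) * width / sub)
            r_i = _ellipse_radius(a * frac, b * frac, th)
            r_o = _ellipse_radius((a + w) * frac_epi, (b + w) * frac_epi, th)
            it = ph.it_at(th, z)
            wall = r_o**2 - r_i**2
            gt[i, k] = 100.0 * np.sum((it / 100.0) * wall) / np.sum(wall)
    ph.stack = stack
    ph.mesh = mesh
    ph.it_bullseye = BullseyeGrid(values=gt, slice_z=levels)
    return ph


def _es_positions(spec: PhantomSpec, points: np.ndarray, it: np.ndarray) -> np.ndarray:
    """Motion model: radial contraction about the long axis, scar akinetic."""
    s = 1.0 - spec.contraction * (1.0 - spec.it_coupling * it / 100.0)
    es = points.copy()
    es[:, 0] *= s
    es[:, 1] *= s
    return es


def sample_emm(
    phantom: Phantom, seed: int = 0, n_points: int | None = None
) -> tuple[EMMMap, np.ndarray]:
    """Sample an EMM acquisition on the phantom endocardium.

    Returns ``(emm, it_truth)`` where ``it_truth`` is the analytic IT
    at each sampled surface location (before contact noise).  Surface
    positions are drawn per-triangle with probability proportional to
    area, boosted by ``oversample_factor`` where IT > 75 %.
    """
    spec = phantom.spec
    n = spec.n_points if n_points is None else n_points
    if n < 10:
        raise ConfigError("need at least 10 EMM points")
    rng = np.random.default_rng(seed)
    mesh = phantom.mesh

    areas = mesh.triangle_areas()
    centroids = mesh.vertices[mesh.triangles].mean(axis=1)
    it_c = phantom.it_at_points(centroids)
    weights = areas * np.where(it_c > 75.0, spec.oversample_factor, 1.0)
    prob = weights / weights.sum()
    tri_idx = rng.choice(len(areas), size=n, p=prob)
    r1, r2 = rng.random(n), rng.random(n)
    swap = r1 + r2 > 1
    r1[swap], r2[swap] = 1 - r1[swap], 1 - r2[swap]
    tri = mesh.vertices[mesh.triangles[tri_idx]]
    pts = tri[:, 0] + r1[:, None] * (tri[:, 1] - tri[:, 0]) + r2[:, None] * (tri[:, 2] - tri[:, 0])

    it = phantom.it_at_points(pts)
    ed = pts + rng.normal(0.0, spec.contact_noise_mm, size=(n, 3))
    es = _es_positions(spec, ed, it)

    uv = spec.uv_healthy_mv - (spec.uv_healthy_mv - spec.uv_scar_mv) * it / 100.0
    uv = np.maximum(uv + rng.normal(0.0, spec.uv_noise_mv, n), 0.0)
    bv = spec.bv_healthy_mv - (spec.bv_healthy_mv - spec.bv_scar_mv) * it / 100.0
    bv = np.maximum(bv + rng.normal(0.0, spec.bv_noise_mv, n), 0.0)
    lls = np.clip(compute_lls(ed, es), -100.0, 100.0)

    emm = EMMMap(
        ids=np.arange(1, n + 1),
        positions=ed,
        uv=uv,
        bv=bv,
        lls=lls,
        included=np.ones(n, dtype=bool),
        trajectories=np.stack([ed, es], axis=1),
    )
    return emm, it


def perturb_rigid(emm: EMMMap, true_transform: RigidTransform) -> EMMMap:
    """Apply a known rigid mis-registration to positions and trajectories."""
    return true_transform.apply_to_emm(emm)


def spec_as_dict(spec: PhantomSpec) -> dict:
    return asdict(spec)
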