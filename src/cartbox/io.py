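"""File dialects and core data containers.

The package exchanges four kinds of artifacts as plain text:

* EMM point tables (CSV) — catheter-based electromechanical mapping
  points with position (mm), unipolar/bipolar voltage (mV) and linear
  local shortening (%).
* Contour stacks (JSON) — per-slice closed polygons of the LV
  endocardium/epicardium at end diastole and end systole, plus optional
  scar contours, with slice z-positions in mm.
* Bullseye matrices (CSV) — slices x 80 circumferential segments.
* Surface meshes (ASCII PLY) — triangulated endocardial surface with
  per-vertex scalar channels ``it`` (infarct transmurality, %) and
  ``wt`` (wall thickening, mm).

Coordinate convention: right-handed frame, x = left, y = posterior,
z = toward the head; all lengths in mm.  Slices are ordered base->apex,
i.e. strictly decreasing z.  Polygons may be given with the last vertex
repeating the first; readers canonicalize to the open representation
with implicit closure.  Numeric file output uses ``%.6g``.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import FormatError, ValidationError

__all__ = [
    "SliceContours",
    "ContourStack",
    "EMMMap",
    "read_emm_table",
    "write_emm_table",
    "read_trajectories",
    "write_trajectories",
    "read_contour_stack",
    "write_contour_stack",
    "read_bullseye",
    "write_bullseye",
    "read_mesh_ply",
    "write_mesh_ply",
]

_FMT = "%.6g"

N_SEGMENTS = 80
"""Number of circumferential segments per slice in every bullseye."""


def _fmt(x: float) -> str:
    return _FMT % x


def _canonical_polygon(coords, what: str) -> np.ndarray:
    """Return an (n, 2) float array in open representation.

    Accepts a sequence of [x, y] pairs; drops a repeated closing vertex.
    """
    arr = np.asarray(coords, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FormatError(f"{what}: polygon must be a sequence of [x, y] pairs")
    if len(arr) >= 2 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    if len(arr) < 3:
        raise FormatError(f"{what}: polygon has fewer than 3 distinct vertices")
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{what}: polygon has non-finite coordinates")
    return arr


def _check_simple(poly: np.ndarray, what: str) -> None:
    if not _ShapelyPolygon(poly).is_valid:
        raise ValidationError(f"{what}: polygon is self-intersecting")


@dataclass
class SliceContours:
    """Contours of one short-axis slice (all coordinates in mm)."""

    z_mm: float
    endo_ed: np.ndarray
    epi_ed: np.ndarray
    endo_es: np.ndarray
    epi_es: np.ndarray
    scar: list = field(default_factory=list)

    def validate(self) -> None:
        for name in ("endo_ed", "epi_ed", "endo_es", "epi_es"):
            poly = getattr(self, name)
            if len(poly) < 3:
                raise ValidationError(f"slice z={self.z_mm}: {name} has <3 vertices")
            _check_simple(poly, f"slice z={self.z_mm}: {name}")
        for i, s in enumerate(self.scar):
            _check_simple(s, f"slice z={self.z_mm}: scar[{i}]")
        # endocardium must lie inside the epicardium (both phases)
        for endo, epi, tag in (
            (self.endo_ed, self.epi_ed, "ED"),
            (self.endo_es, self.epi_es, "ES"),
        ):
            shell = _ShapelyPolygon(epi)
            inside = contains_xy(shell, endo[:, 0], endo[:, 1])
            if not np.all(inside):
                raise ValidationError(
                    f"slice z={self.z_mm}: {tag} endocardial vertex outside epicardium"
                )


@dataclass
class ContourStack:
    """Stack of short-axis slices ordered base->apex (decreasing z)."""

    slices: list
    pixel_spacing_mm: float = 0.25

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def slice_z(self) -> np.ndarray:
        return np.array([s.z_mm for s in self.slices])

    def validate(self) -> None:
        if self.pixel_spacing_mm <= 0:
            raise ValidationError("pixel_spacing_mm must be positive")
        z = self.slice_z
        if len(z) and not np.all(np.diff(z) < 0):
            raise ValidationError("slice z-positions must be strictly decreasing base->apex")
        for s in self.slices:
            s.validate()


@dataclass
class EMMMap:
    """Electromechanical mapping point set.

    ``positions`` are end-diastolic catheter-tip locations (mm);
    ``trajectories`` (optional) hold the per-point positions over the
    cardiac cycle as an (n, n_phases, 3) array whose first phase is end
    diastole and last phase is maximal systole.
    """

    ids: np.ndarray
    positions: np.ndarray
    uv: np.ndarray
    bv: np.ndarray
    lls: np.ndarray
    included: np.ndarray
    trajectories: np.ndarray | None = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        for name in ("uv", "bv", "lls"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.included = np.asarray(self.included, dtype=bool)

    @property
    def n_points(self) -> int:
        return len(self.ids)

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def validate(self) -> None:
        n = self.n_points
        if len(np.unique(self.ids)) != n:
            raise ValidationError("EMM point ids are not unique")
        if self.positions.shape != (n, 3) or not np.all(np.isfinite(self.positions)):
            raise ValidationError("EMM positions must be finite (n, 3)")
        if np.any(self.uv < 0) or np.any(self.bv < 0):
            raise ValidationError("voltages must be non-negative")
        if np.any(np.abs(self.lls[np.isfinite(self.lls)]) > 100):
            raise ValidationError("LLS must lie in [-100, 100] %")
        if self.trajectories is not None and self.trajectories.shape[::2] != (n, 3):
            raise ValidationError("trajectories must have shape (n, n_phases, 3)")

    def copy(self) -> "EMMMap":
        return EMMMap(
            self.ids.copy(),
            self.positions.copy(),
            self.uv.copy(),
            self.bv.copy(),
            self.lls.copy(),
            self.included.copy(),
            None if self.trajectories is None else self.trajectories.copy(),
        )


# ---------------------------------------------------------------------------
# EMM CSV dialect: header  id,x,y,z,uv,bv,lls
# ---------------------------------------------------------------------------

_EMM_COLUMNS = ["id", "x", "y", "z", "uv", "bv", "lls"]


def read_emm_table(path) -> EMMMap:
    """Read an EMM point table (CSV with header ``id,x,y,z,uv,bv,lls``).

    Every data row becomes one point; ``included`` is initialized to
    True and row order is preserved.  Malformed input raises
    :class:`~cartbox.errors.FormatError` naming the offending column or
    row.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in _EMM_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column {col}")
    out = {}
    for col in _EMM_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if len(bad):
            raise FormatError(f"non-numeric value in column {col}, row {bad[0] + 1}")
        if vals.isna().any():
            raise FormatError(
                f"empty cell in column {col}, row {int(np.nonzero(vals.isna().to_numpy())[0][0]) + 1}"
            )
        out[col] = vals.to_numpy(dtype=float)
    ids = out["id"]
    if np.any(ids != np.round(ids)):
        raise FormatError("column id must contain integers")
    ids = ids.astype(int)
    if len(np.unique(ids)) != len(ids):
        raise FormatError("duplicate id in EMM table")
    emm = EMMMap(
        ids=ids,
        positions=np.column_stack([out["x"], out["y"], out["z"]]),
        uv=out["uv"],
        bv=out["bv"],
        lls=out["lls"],
        included=np.ones(len(ids), dtype=bool),
    )
    emm.validate()
    return emm


def write_emm_table(emm: EMMMap, path) -> None:
    """Write an EMM point table in the CSV dialect read by :func:`read_emm_table`."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_EMM_COLUMNS)
        for i in range(emm.n_points):
            x, y, z = emm.positions[i]
            w.writerow(
                [emm.ids[i]]
                + [_fmt(v) for v in (x, y, z, emm.uv[i], emm.bv[i], emm.lls[i])]
            )


def read_trajectories(path, emm: EMMMap | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Read a trajectory table (CSV ``id,phase,x,y,z``).

    Returns ``(ids, trajectories)`` where trajectories has shape
    (n, n_phases, 3) with phases sorted ascending.  If ``emm`` is given,
    its ``trajectories`` field is filled in place (ids must match).
    """
    df = pd.read_csv(path)
    for col in ("id", "phase", "x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"missing column {col}")
    ids = np.array(sorted(df["id"].unique()), dtype=int)
    phases = np.array(sorted(df["phase"].unique()))
    n, p = len(ids), len(phases)
    traj = np.full((n, p, 3), np.nan)
    id_index = {v: i for i, v in enumerate(ids)}
    ph_index = {v: i for i, v in enumerate(phases)}
    for row in df.itertuples(index=False):
        traj[id_index[int(row.id)], ph_index[row.phase]] = (row.x, row.y, row.z)
    if np.any(~np.isfinite(traj)):
        raise FormatError("trajectory table is ragged: not all ids cover all phases")
    if emm is not None:
        if not np.array_equal(np.sort(emm.ids), ids):
            raise FormatError("trajectory ids do not match EMM table ids")
        traj = traj[np.array([id_index[i] for i in emm.ids])]
        emm.trajectories = traj
    return ids, traj


def write_trajectories(ids: np.ndarray, trajectories: np.ndarray, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "phase", "x", "y", "z"])
        for i, pid in enumerate(ids):
            for ph in range(trajectories.shape[1]):
                w.writerow([int(pid), ph] + [_fmt(v) for v in trajectories[i, ph]])


# ---------------------------------------------------------------------------
# Contour stack JSON dialect
# ---------------------------------------------------------------------------


def read_contour_stack(path) -> ContourStack:
    """Read a contour stack from its JSON dialect.

    Schema: ``{"slices": [{"z": ..., "endo_ed": [[x, y], ...], "epi_ed":
    [...], "endo_es": [...], "epi_es": [...], "scar": [[[x, y], ...], ...]},
    ...], "pixel_spacing": ...}``.  Slices are sorted base->apex
    (decreasing z) and all structural invariants are enforced.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if "slices" not in doc:
        raise FormatError("missing key 'slices'")
    slices = []
    for k, s in enumerate(doc["slices"]):
        for key in ("z", "endo_ed", "epi_ed", "endo_es", "epi_es"):
            if key not in s:
                raise FormatError(f"slice {k}: missing key '{key}'")
        slices.append(
            SliceContours(
                z_mm=float(s["z"]),
                endo_ed=_canonical_polygon(s["endo_ed"], f"slice {k} endo_ed"),
                epi_ed=_canonical_polygon(s["epi_ed"], f"slice {k} epi_ed"),
                endo_es=_canonical_polygon(s["endo_es"], f"slice {k} endo_es"),
                epi_es=_canonical_polygon(s["epi_es"], f"slice {k} epi_es"),
                scar=[
                    _canonical_polygon(p, f"slice {k} scar[{j}]")
                    for j, p in enumerate(s.get("scar", []))
                ],
            )
        )
    z = np.array([s.z_mm for s in slices])
    if len(np.unique(z)) != len(z):
        raise ValidationError("duplicate slice z-positions: z must be strictly monotone")
    slices.sort(key=lambda s: -s.z_mm)
    stack = ContourStack(slices=slices, pixel_spacing_mm=float(doc.get("pixel_spacing", 0.25)))
    stack.validate()
    return stack


def write_contour_stack(stack: ContourStack, path) -> None:
    def poly(a):
        return [[float(_fmt(x)), float(_fmt(y))] for x, y in a]

    doc = {
        "pixel_spacing": float(_fmt(stack.pixel_spacing_mm)),
        "slices": [
            {
                "z": float(_fmt(s.z_mm)),
                "endo_ed": poly(s.endo_ed),
                "epi_ed": poly(s.epi_ed),
                "endo_es": poly(s.endo_es),
                "epi_es": poly(s.epi_es),
                "scar": [poly(p) for p in s.scar],
            }
            for s in stack.slices
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Bullseye CSV dialect
# ---------------------------------------------------------------------------


def write_bullseye(values: np.ndarray, path) -> None:
    """Write a slices x 80 bullseye matrix as CSV.

    Rows are slices base->apex; the 80 columns are circumferential
    segments starting at the anterior-septal junction (+x axis),
    proceeding counterclockwise when viewed from the apex.  Missing
    values (NaN) are written as empty cells.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != N_SEGMENTS:
        raise FormatError(f"bullseye rows must have exactly {N_SEGMENTS} values")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for row in values:
            w.writerow(["" if not np.isfinite(v) else _fmt(v) for v in row])


def read_bullseye(path) -> np.ndarray:
    rows = []
    with open(path, newline="") as fh:
        for line in csv.reader(fh):
            if not line:
                continue
            if len(line) != N_SEGMENTS:
                raise FormatError(f"bullseye row has {len(line)} cells, expected {N_SEGMENTS}")
            rows.append([np.nan if c == "" else float(c) for c in line])
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# ASCII PLY mesh dialect with per-vertex scalar channels
# ---------------------------------------------------------------------------


def write_mesh_ply(mesh, path) -> None:
    """Write a surface mesh as ASCII PLY.

    Vertex properties are x, y, z plus one float property per scalar
    channel on the mesh (``it``, ``wt``, ...).  Channel NaNs round-trip.
    """
    channels = list(mesh.vertex_channels)
    buf = _io.StringIO()
    buf.write("ply\nformat ascii 1.0\n")
    buf.write(f"element vertex {len(mesh.vertices)}\n")
    for p in ("x", "y", "z"):
        buf.write(f"property float {p}\n")
    for c in channels:
        buf.write(f"property float {c}\n")
    buf.write(f"element face {len(mesh.triangles)}\n")
    buf.write("property list uchar int vertex_indices\nend_header\n")
    chan_arrays = [mesh.vertex_channels[c] for c in channels]
    for i, v in enumerate(mesh.vertices):
        cells = [_fmt(x) for x in v] + [_fmt(a[i]) for a in chan_arrays]
        buf.write(" ".join(cells) + "\n")
    for t in mesh.triangles:
        buf.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_mesh_ply(path):
    """Read an ASCII PLY written by :func:`write_mesh_ply`.

    Returns ``(vertices, triangles, channels)`` where channels maps
    property name -> per-vertex array.  Mesh metadata (apex, basal
    plane, slice indices) is not stored in PLY; rebuild via
    :mod:`cartbox.mesh` when needed.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise FormatError("not a PLY file")
    n_vert = n_face = None
    props: list[str] = []
    i = 1
    element = None
    while i < len(lines):
        tok = lines[i].split()
        i += 1
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise FormatError("only ASCII PLY is supported")
        if tok[0] == "element":
            element = tok[1]
            if tok[1] == "vertex":
                n_vert = int(tok[2])
            elif tok[1] == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
            props.append(tok[-1])
        elif tok[0] == "end_header":
            break
    if n_vert is None or n_face is None:
        raise FormatError("PLY header lacks vertex or face element")
    body = lines[i:]
    vdata = np.array([[float(x) for x in ln.split()] for ln in body[:n_vert]])
    if vdata.shape != (n_vert, len(props)):
        raise FormatError("PLY vertex block does not match header")
    faces = []
    for ln in body[n_vert : n_vert + n_face]:
        tok = ln.split()
        if int(tok[0]) != 3:
            raise FormatError("only triangular faces are supported")
        faces.append([int(x) for x in tok[1:4]])
    base = {p: vdata[:, k] for k, p in enumerate(props)}
    vertices = np.column_stack([base.pop("x"), base.pop("y"), base.pop("z")])
    return vertices, np.asarray(faces, dtype=int), base
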