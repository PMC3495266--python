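"""Triangle-mesh data model, I/O and geometric primitives.

All downstream morphometry assumes *corresponded* meshes: every surface in a
cohort shares one template topology (same vertex count, same face list), so
that vertex ``i`` marks the same anatomical location on every subject at every
visit. This module provides the mesh container, legacy-VTK / PLY I/O, enclosed
volume, outward vertex normals, and the correspondence check that guards that
assumption.
"""
from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TriangleMesh",
    "CorrespondenceReport",
    "MeshFormatError",
    "TopologyError",
    "DimensionError",
    "read_surface",
    "write_surface",
    "enclosed_volume",
    "vertex_normals",
    "validate_correspondence",
    "STUDY_TOTAL_VERTICES",
]

#: Total vertex count (both hemispheres) of the original study template.
STUDY_TOTAL_VERTICES = 13222


class MeshFormatError(ValueError):
    """A surface file could not be parsed as the named format."""


class TopologyError(ValueError):
    """The mesh is not a closed, orientable triangulated 2-manifold."""


class DimensionError(ValueError):
    """An attached per-vertex field has the wrong length."""


@dataclass
class TriangleMesh:
    """A triangulated surface with optional per-vertex scalar fields.

    Parameters
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array, 0-based vertex indices
    hemisphere : {"left", "right"}
    topology_id : opaque token identifying the shared template topology;
        derived from the face list when not given.
    point_data : named per-vertex scalar fields (each length V).
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: str = "left"
    topology_id: str | None = None
    point_data: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DimensionError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be triangles (F, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshFormatError("face index out of range [0, V)")
        if self.topology_id is None:
            h = hashlib.sha1()
            h.update(np.int64(len(self.vertices)).tobytes())
            h.update(np.ascontiguousarray(self.faces).tobytes())
            self.topology_id = h.hexdigest()[:16]
        for name, vals in self.point_data.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (len(self.vertices),):
                raise DimensionError(
                    f"point_data[{name!r}] has length {vals.shape}, expected V={len(self.vertices)}"
                )
            self.point_data[name] = vals

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self, vertices: np.ndarray | None = None) -> "TriangleMesh":
        """Copy, optionally replacing coordinates (topology is shared)."""
        return TriangleMesh(
            vertices=np.array(self.vertices if vertices is None else vertices),
            faces=self.faces,
            hemisphere=self.hemisphere,
            topology_id=self.topology_id,
            point_data=dict(self.point_data),
        )


@dataclass
class CorrespondenceReport:
    ok: bool
    mismatches: list  # of (mesh id, reason)


# ---------------------------------------------------------------------------
# topology helpers


def _check_closed_orientable(mesh: TriangleMesh) -> None:
    """Raise TopologyError unless every edge is shared by exactly two faces
    with opposite orientation (closed, consistently wound, orientable)."""
    f = mesh.faces
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    key = directed[:, 0] * (mesh.n_vertices + 1) + directed[:, 1]
    if len(np.unique(key)) != len(key):
        raise TopologyError("duplicated directed edge: inconsistent winding or non-manifold")
    und = np.sort(directed, axis=1)
    ukey = und[:, 0] * (mesh.n_vertices + 1) + und[:, 1]
    _, counts = np.unique(ukey, return_counts=True)
    if not np.all(counts == 2):
        raise TopologyError("mesh is not closed: some edges not shared by exactly 2 faces")


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Volume (mm^3) enclosed by a closed orientable mesh.

    Divergence-theorem signed-tetrahedron sum: each face contributes
    det(v0, v1, v2)/6 with respect to the origin; the absolute value of the
    total makes the result independent of global orientation, and the signed
    sum itself is translation invariant for a closed surface.
    """
    _check_closed_orientable(mesh)
    v = mesh.vertices
    t = v[mesh.faces]  # (F, 3, 3)
    signed = np.einsum("fi,fi->f", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0
    return float(abs(signed.sum()))


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Outward unit normals, area-weighted over incident faces.

    Degenerate (zero-area) faces are skipped with a warning. If the winding
    convention points inward (negative mean dot product with the direction
    away from the centroid), all normals are flipped so they point outward.
    """
    _check_closed_orientable(mesh)
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area*n
    areas = np.linalg.norm(fn, axis=1)
    degenerate = areas < 1e-30
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} degenerate face(s) skipped in normal computation")
        fn = fn[~degenerate]
        f = f[~degenerate]
    acc = np.zeros_like(v)
    for c in range(3):
        np.add.at(acc, f[:, c], fn)
    norms = np.linalg.norm(acc, axis=1)
    norms[norms == 0] = 1.0
    n = acc / norms[:, None]
    centroid = v.mean(axis=0)
    if np.mean(np.einsum("ij,ij->i", n, v - centroid)) < 0:
        n = -n
    return n


def validate_correspondence(meshes: list[TriangleMesh]) -> CorrespondenceReport:
    """Check that all meshes share the reference's vertex count, face list and
    hemisphere partition. The first mesh of each hemisphere is the reference."""
    if not meshes:
        raise ValueError("need at least one mesh")
    refs: dict[str, TriangleMesh] = {}
    mismatches = []
    for i, m in enumerate(meshes):
        ref = refs.setdefault(m.hemisphere, m)
        if m is ref:
            continue
        mid = f"mesh[{i}]({m.hemisphere})"
        if m.n_vertices != ref.n_vertices:
            mismatches.append((mid, f"vertex count {m.n_vertices} != {ref.n_vertices}"))
            continue
        if m.faces.shape != ref.faces.shape or not np.array_equal(m.faces, ref.faces):
            mismatches.append((mid, "face list differs from reference"))
        elif m.topology_id != ref.topology_id:
            mismatches.append((mid, "topology_id differs"))
    return CorrespondenceReport(ok=not mismatches, mismatches=mismatches)


# ---------------------------------------------------------------------------
# I/O: legacy VTK ASCII polydata (read/write) and ascii PLY (read-only)

_HEMI_RE = re.compile(r"_(left|right)_", re.IGNORECASE)


def _hemi_from_path(path: Path) -> str | None:
    m = _HEMI_RE.search(path.name)
    return m.group(1).lower() if m else None


def write_surface(
    mesh: TriangleMesh,
    path,
    scalars: dict | None = None,
    format: str = "vtk-legacy-ascii",
) -> Path:
    """Write a mesh (plus optional named per-vertex scalar fields) to disk.

    Legacy-VTK ASCII polydata is the canonical format: human readable and
    viewable in standard tools. Coordinates and scalars are printed with 17
    significant digits so a read-back reproduces float64 values exactly.
    """
    if format != "vtk-legacy-ascii":
        raise MeshFormatError(f"unsupported write format: {format}")
    path = Path(path)
    fields = dict(mesh.point_data)
    if scalars:
        fields.update(scalars)
    for name, vals in fields.items():
        vals = np.asarray(vals, dtype=float)
        if vals.shape != (mesh.n_vertices,):
            raise DimensionError(f"scalar field {name!r} length != V")
        fields[name] = vals
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"hippomorph surface hemisphere={mesh.hemisphere} topology={mesh.topology_id}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")
        if fields:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, vals in fields.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for x in vals:
                    fh.write(f"{x:.17g}\n")
    return path


def read_surface(path, format: str | None = None, hemisphere: str | None = None) -> TriangleMesh:
    """Read a surface from legacy-VTK ASCII polydata or ascii PLY.

    The format is inferred from the extension when not given. Vertex order is
    preserved exactly as stored. Per-vertex SCALARS fields (VTK) are attached
    as ``point_data``. Hemisphere is taken from the argument, the VTK title
    line, or a ``_left_`` / ``_right_`` filename token, in that order.
    """
    path = Path(path)
    if format is None:
        format = "ply" if path.suffix.lower() == ".ply" else "vtk-legacy-ascii"
    if format == "ply":
        return _read_ply(path, hemisphere)
    if format == "vtk-legacy-ascii":
        return _read_vtk(path, hemisphere)
    raise MeshFormatError(f"unsupported read format: {format}")


def _read_vtk(path: Path, hemisphere: str | None) -> TriangleMesh:
    lines = path.read_text().splitlines()
    it = iter(enumerate(lines, start=1))

    def next_content():
        for ln, line in it:
            if line.strip():
                return ln, line.strip()
        raise MeshFormatError(f"{path}: unexpected end of file")

    ln, magic = next_content()
    if not magic.startswith("# vtk DataFile"):
        raise MeshFormatError(f"{path}:{ln}: not a legacy VTK file")
    _, title = next_content()
    ln, enc = next_content()
    if enc.upper() != "ASCII":
        raise MeshFormatError(f"{path}:{ln}: only ASCII VTK supported")
    ln, ds = next_content()
    if ds.upper() != "DATASET POLYDATA":
        raise MeshFormatError(f"{path}:{ln}: expected DATASET POLYDATA")
    ln, pts = next_content()
    m = re.match(r"POINTS\s+(\d+)\s+\w+", pts)
    if not m:
        raise MeshFormatError(f"{path}:{ln}: expected POINTS header")
    nv = int(m.group(1))
    coords: list[float] = []
    while len(coords) < 3 * nv:
        ln, line = next_content()
        coords.extend(float(t) for t in line.split())
    vertices = np.array(coords, dtype=float).reshape(nv, 3)
    ln, poly = next_content()
    m = re.match(r"POLYGONS\s+(\d+)\s+(\d+)", poly)
    if not m:
        raise MeshFormatError(f"{path}:{ln}: expected POLYGONS header")
    nf = int(m.group(1))
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        ln, line = next_content()
        toks = line.split()
        if toks[0] != "3":
            raise MeshFormatError(f"{path}:{ln}: non-triangular face (size {toks[0]})")
        faces[i] = [int(toks[1]), int(toks[2]), int(toks[3])]
    point_data: dict = {}
    try:
        while True:
            ln, line = next_content()
            if line.startswith("POINT_DATA"):
                continue
            m = re.match(r"SCALARS\s+(\S+)\s+\w+", line)
            if not m:
                continue
            name = m.group(1)
            next_content()  # LOOKUP_TABLE
            vals: list[float] = []
            while len(vals) < nv:
                _, vline = next_content()
                vals.extend(float(t) for t in vline.split())
            point_data[name] = np.array(vals)
    except MeshFormatError:
        pass  # normal end of file
    hemi = hemisphere
    if hemi is None:
        m = re.search(r"hemisphere=(\w+)", title)
        hemi = m.group(1) if m else _hemi_from_path(path)
    return TriangleMesh(vertices, faces, hemisphere=hemi or "left", point_data=point_data)


def _read_ply(path: Path, hemisphere: str | None) -> TriangleMesh:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshFormatError(f"{path}:1: not a PLY file")
    nv = nf = None
    i = 1
    elements: list[tuple[str, int]] = []
    while i < len(lines):
        t = lines[i].split()
        if not t:
            i += 1
            continue
        if t[0] == "format" and t[1] != "ascii":
            raise MeshFormatError(f"{path}:{i + 1}: only ascii PLY supported")
        if t[0] == "element":
            elements.append((t[1], int(t[2])))
            if t[1] == "vertex":
                nv = int(t[2])
            elif t[1] == "face":
                nf = int(t[2])
        if t[0] == "end_header":
            i += 1
            break
        i += 1
    else:
        raise MeshFormatError(f"{path}: missing end_header")
    if nv is None or nf is None:
        raise MeshFormatError(f"{path}: missing vertex/face elements")
    vertices = np.empty((nv, 3))
    faces = np.empty((nf, 3), dtype=np.int64)
    row = 0
    for name, count in elements:
        for k in range(count):
            toks = lines[i + k].split()
            if name == "vertex":
                vertices[k] = [float(toks[0]), float(toks[1]), float(toks[2])]
            elif name == "face":
                if toks[0] != "3":
                    raise MeshFormatError(f"{path}:{i + k + 1}: non-triangular face")
                faces[k] = [int(toks[1]), int(toks[2]), int(toks[3])]
        i += count
        row += count
    hemi = hemisphere or _hemi_from_path(path) or "left"
    return TriangleMesh(vertices, faces, hemisphere=hemi)
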