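"""Triangulated-surface data model, geometry, and mesh file I/O.

All coordinates are world millimetres.  Faces are 0-based vertex index
triples.  The currents representation of a mesh — one centroid and one
area-weighted normal per triangle — is the unit that surface matching
operates on: the normal of face ``(v1, v2, v3)`` is ``0.5 * (v2-v1) x
(v3-v1)``, so its Euclidean norm equals the triangle area.  Area weighting
(rather than unit normals) makes the kernel inner product stable under mesh
refinement.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh


@dataclass(frozen=True)
class TriMesh:
    """A triangulated surface: ``vertices`` (n, 3) float64 mm, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array of vertex triples")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        """Same connectivity, new vertex positions."""
        return TriMesh(np.asarray(vertices, dtype=np.float64), self.faces)

    def flipped(self) -> "TriMesh":
        """Reverse the orientation of every face."""
        return TriMesh(self.vertices, self.faces[:, ::-1])


@dataclass(frozen=True)
class CurrentRep:
    """Currents representation: per-face centroids and area-weighted normals."""

    centers: np.ndarray
    normals: np.ndarray

    @property
    def areas(self) -> np.ndarray:
        return np.linalg.norm(self.normals, axis=1)


def face_vertex_arrays(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    v = mesh.vertices
    f = mesh.faces
    return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]


def compute_current(mesh: TriMesh, *, degenerate_tol: float = 1e-12) -> CurrentRep:
    """Centroid and area-weighted normal of every face.

    Raises ``ValueError`` naming the first degenerate (zero-area) face.
    """
    p1, p2, p3 = face_vertex_arrays(mesh)
    centers = (p1 + p2 + p3) / 3.0
    normals = 0.5 * np.cross(p2 - p1, p3 - p1)
    areas = np.linalg.norm(normals, axis=1)
    bad = np.flatnonzero(areas <= degenerate_tol)
    if bad.size:
        raise ValueError(f"degenerate (zero-area) face at index {bad[0]}")
    return CurrentRep(centers=centers, normals=normals)


def is_closed(mesh: TriMesh) -> bool:
    """True when every edge is shared by exactly two faces."""
    f = mesh.faces
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def mesh_volume(mesh: TriMesh, *, return_orientation: bool = False):
    """Enclosed volume of a closed mesh via the divergence theorem.

    The signed volume is ``sum(c_f . N_f) / 3`` over faces; the absolute
    value is returned.  ``return_orientation`` additionally reports whether
    the stored face orientation is outward (signed volume positive).
    """
    if not is_closed(mesh):
        raise ValueError("mesh_volume requires a closed mesh (every edge shared by two faces)")
    cur = compute_current(mesh)
    signed = float(np.sum(cur.centers * cur.normals) / 3.0)
    if return_orientation:
        return abs(signed), signed > 0
    return abs(signed)


def contains_points(mesh: TriMesh, points: np.ndarray,
                    chunk: int = 2048) -> np.ndarray:
    """Point-in-mesh test for a closed, outward-oriented mesh.

    Uses the generalized winding number: the summed signed solid angle of
    every face seen from the query point is ~4*pi inside and ~0 outside
    (van Oosterom-Strackee formula per triangle).  Exact up to floating
    point; no spatial index required.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    v = mesh.vertices
    f = mesh.faces
    out = np.empty(len(pts), dtype=bool)
    for s in range(0, len(pts), chunk):
        p = pts[s:s + chunk]
        a = v[f[:, 0]][None] - p[:, None]          # (q, m, 3)
        b = v[f[:, 1]][None] - p[:, None]
        c = v[f[:, 2]][None] - p[:, None]
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        num = np.einsum("qmi,qmi->qm", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("qmi,qmi->qm", a, b) * lc
               + np.einsum("qmi,qmi->qm", b, c) * la
               + np.einsum("qmi,qmi->qm", c, a) * lb)
        omega = 2.0 * np.arctan2(num, den)
        out[s:s + chunk] = omega.sum(axis=1) / (4.0 * np.pi) > 0.5
    return out


# ---------------------------------------------------------------------------
# File I/O: VTK legacy ASCII polydata (in-repo), PLY and OFF (via trimesh)
# ---------------------------------------------------------------------------

def write_mesh(mesh: TriMesh, path: str | os.PathLike,
               point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a mesh as VTK legacy ASCII polydata, PLY, or OFF (by extension).

    ``point_data`` (per-vertex scalar arrays) is only supported for ``.vtk``.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".vtk":
        _write_vtk(mesh, path, point_data or {})
    elif ext in (".ply", ".off"):
        if point_data:
            raise ValueError("per-vertex scalar arrays are only written to .vtk")
        tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        tm.export(path, file_type="ply" if ext == ".ply" else "off",
                  **({"encoding": "ascii"} if ext == ".ply" else {}))
    else:
        raise ValueError(f"unsupported mesh format: {ext!r} (use .vtk, .ply, or .off)")


def read_mesh(path: str | os.PathLike) -> TriMesh:
    """Read a VTK legacy polydata, PLY, or OFF mesh.  Non-triangular cells error."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".vtk":
        return _read_vtk(path)[0]
    if ext in (".ply", ".off"):
        tm = _trimesh.load(path, process=False, force="mesh")
        faces = np.asarray(tm.faces)
        # trimesh triangulates silently; detect non-triangle input from the raw file
        if ext == ".off":
            _check_off_triangular(path)
        elif ext == ".ply":
            _check_ply_triangular(path)
        return TriMesh(np.asarray(tm.vertices, dtype=np.float64), faces)
    raise ValueError(f"unsupported mesh format: {ext!r} (use .vtk, .ply, or .off)")


def read_mesh_with_data(path: str | os.PathLike) -> tuple[TriMesh, dict[str, np.ndarray]]:
    """Read a VTK legacy polydata mesh together with its per-vertex scalar arrays."""
    return _read_vtk(os.fspath(path))


def _write_vtk(mesh: TriMesh, path: str, point_data: dict[str, np.ndarray]) -> None:
    n, m = mesh.n_vertices, mesh.n_faces
    lines = [
        "# vtk DataFile Version 3.0",
        "tractsurf surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{x:.17g}" for x in row) for row in mesh.vertices]
    lines.append(f"POLYGONS {m} {4 * m}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=np.float64)
            if values.shape != (n,):
                raise ValueError(f"point-data array {name!r} must have one value per vertex")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{x:.17g}" for x in values]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_vtk(path: str) -> tuple[TriMesh, dict[str, np.ndarray]]:
    with open(path) as fh:
        tokens = fh.read().split()
    up = [t.upper() for t in tokens]

    def _find(keyword: str, start: int = 0) -> int:
        try:
            return up.index(keyword, start)
        except ValueError:
            return -1

    i = _find("POINTS")
    if i < 0:
        raise ValueError(f"{path}: no POINTS section (not legacy polydata?)")
    n = int(tokens[i + 1])
    coords = np.array(tokens[i + 3:i + 3 + 3 * n], dtype=np.float64).reshape(n, 3)

    j = _find("POLYGONS")
    if j < 0:
        raise ValueError(f"{path}: no POLYGONS section")
    m = int(tokens[j + 1])
    total = int(tokens[j + 2])
    cell_tokens = np.array(tokens[j + 3:j + 3 + total], dtype=np.int64)
    faces = np.empty((m, 3), dtype=np.int64)
    pos = 0
    for k in range(m):
        cnt = cell_tokens[pos]
        if cnt != 3:
            raise ValueError(f"{path}: non-triangular cell ({cnt} vertices) at polygon {k}")
        faces[k] = cell_tokens[pos + 1:pos + 4]
        pos += 4
    mesh = TriMesh(coords, faces)

    data: dict[str, np.ndarray] = {}
    k = _find("POINT_DATA")
    while k >= 0:
        s = _find("SCALARS", k)
        if s < 0:
            break
        name = tokens[s + 1]
        ncomp = int(tokens[s + 3]) if tokens[s + 3].isdigit() else 1
        lut = _find("LOOKUP_TABLE", s)
        start = lut + 2 if lut >= 0 else s + 4
        data[name] = np.array(tokens[start:start + n * ncomp], dtype=np.float64)
        k = s + 1
    return mesh, data


def _check_off_triangular(path: str) -> None:
    with open(path) as fh:
        toks = [t for line in fh
                for t in (line.split("#", 1)[0].split() if not line.startswith("OFF") else [])]
    nv, nf = int(toks[0]), int(toks[1])
    pos = 3 + 3 * nv
    for k in range(nf):
        cnt = int(toks[pos])
        if cnt != 3:
            raise ValueError(f"{path}: non-triangular cell ({cnt} vertices) at face {k}")
        pos += cnt + 1


def _check_ply_triangular(path: str) -> None:
    with open(path, "rb") as fh:
        header = fh.read(4096).decode("latin-1")
    if "format ascii" not in header:
        return  # binary PLY: trust trimesh's parse
    with open(path) as fh:
        lines = fh.read().splitlines()
    nv = nf = 0
    body = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            nv = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            nf = int(parts[2])
        elif parts[:1] == ["end_header"]:
            body = i + 1
            break
    for k in range(nf):
        cnt = int(lines[body + nv + k].split()[0])
        if cnt != 3:
            raise ValueError(f"{path}: non-triangular cell ({cnt} vertices) at face {k}")


# ---------------------------------------------------------------------------
# Primitive meshes (test fixtures and synthetic-atlas building blocks)
# ---------------------------------------------------------------------------

def icosphere(radius: float = 1.0, subdivisions: int = 3,
              center: np.ndarray | None = None) -> TriMesh:
    """Geodesic sphere with outward-oriented faces."""
    tm = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(tm.vertices, dtype=np.float64)
    if center is not None:
        v = v + np.asarray(center, dtype=np.float64)
    return TriMesh(v, np.asarray(tm.faces))


def box_mesh(extents=(1.0, 1.0, 1.0), center=(0.0, 0.0, 0.0)) -> TriMesh:
    """Axis-aligned box as twelve outward-oriented triangles."""
    tm = _trimesh.creation.box(extents=extents)
    v = np.asarray(tm.vertices, dtype=np.float64) + np.asarray(center, dtype=np.float64)
    return TriMesh(v, np.asarray(tm.faces))
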