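"""Triangle-mesh container, STL reading/writing and printability diagnostics.

A mesh is stored the way the sweep pipeline produces it: an ``n x 3`` vertex
matrix in millimetres and an ``m x 3`` connectivity matrix of 0-based vertex
indices.  STL files carry no indices and duplicate every shared vertex, so
reading merges duplicates within a small tolerance; this is what makes
edge-based watertightness checks meaningful.  Facet normals stored in the
file are ignored and recomputed from counter-clockwise winding on write.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import StlParseError, DegenerateGeometryError

#: Distance (mm) below which two STL vertices are considered the same point.
MERGE_TOLERANCE_MM = 1e-6


@dataclass
class TriangleMesh:
    """Triangulated surface: ``vertices`` (n, 3) mm and ``faces`` (m, 3) indices."""

    vertices: np.ndarray
    faces: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- validity ---------------------------------------------------------
    def validate(self) -> None:
        if self.vertices.size and not np.isfinite(self.vertices).all():
            raise DegenerateGeometryError("mesh has non-finite vertex coordinates")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise DegenerateGeometryError("face index out of range")
            f = self.faces
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
                raise DegenerateGeometryError("face repeats a vertex index")

    # -- derived geometry --------------------------------------------------
    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates per face."""
        return self.vertices[self.faces]

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        if normalize:
            lens = np.linalg.norm(n, axis=1, keepdims=True)
            lens[lens == 0] = 1.0
            n = n / lens
        return n

    def volume(self) -> float:
        """Signed volume by the divergence theorem (positive for outward winding)."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), dict(self.metadata))


@dataclass
class MeshDiagnostics:
    """Printability report: topology and triangle edge-length statistics."""

    is_watertight: bool
    is_consistently_oriented: bool
    euler_characteristic: int
    genus: int
    triangle_count: int
    min_edge: float
    max_edge: float
    mean_edge: float


def merge_duplicate_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = MERGE_TOLERANCE_MM
) -> tuple[np.ndarray, np.ndarray]:
    """Weld vertices closer than ``tol`` and drop degenerate faces.

    Union-find over KD-tree close pairs, so chains of nearby duplicates
    collapse to a single representative.
    """
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    n = len(vertices)
    if n == 0:
        return vertices, faces
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(vertices)
    for i, j in tree.query_pairs(tol):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(n)])
    uniq, remap = np.unique(roots, return_inverse=True)
    new_vertices = vertices[uniq]
    new_faces = remap[faces]
    keep = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return new_vertices, new_faces[keep]


# ---------------------------------------------------------------------------
# STL reading
# ---------------------------------------------------------------------------

def _looks_ascii(head: bytes) -> bool:
    return head.lstrip().lower().startswith(b"solid") and b"facet" in head


def read_stl(path: str | Path, merge_tol: float = MERGE_TOLERANCE_MM) -> TriangleMesh:
    """Read an ASCII or binary STL file into a merged-vertex mesh."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 15:
        raise StlParseError(f"{path}: file too short ({len(raw)} bytes) to be STL")
    if _looks_ascii(raw[:1024]):
        tris = _parse_ascii(raw, path)
    else:
        tris = _parse_binary(raw, path)
    flat = tris.reshape(-1, 3)
    faces = np.arange(len(flat), dtype=np.int64).reshape(-1, 3)
    v, f = merge_duplicate_vertices(flat, faces, merge_tol)
    mesh = TriangleMesh(v, f)
    mesh.validate()
    return mesh


def _parse_ascii(raw: bytes, path: Path) -> np.ndarray:
    tris: list[list[float]] = []
    current: list[float] = []
    in_loop = False
    for lineno, line in enumerate(raw.decode("ascii", errors="replace").splitlines(), 1):
        tokens = line.split()
        if not tokens:
            continue
        kw = tokens[0].lower()
        if kw == "vertex":
            if len(tokens) != 4:
                raise StlParseError(f"{path}: line {lineno}: vertex needs 3 coordinates")
            if not in_loop:
                raise StlParseError(f"{path}: line {lineno}: vertex outside 'outer loop'")
            try:
                current.extend(float(t) for t in tokens[1:4])
            except ValueError as exc:
                raise StlParseError(f"{path}: line {lineno}: bad vertex number: {exc}") from exc
        elif kw == "outer":
            in_loop = True
            current = []
        elif kw == "endloop":
            if len(current) != 9:
                raise StlParseError(
                    f"{path}: line {lineno}: facet has {len(current) // 3} vertices, expected 3"
                )
            tris.append(current)
            in_loop = False
        elif kw in ("solid", "endsolid", "facet", "endfacet"):
            continue
        else:
            raise StlParseError(f"{path}: line {lineno}: unexpected token {tokens[0]!r}")
    if not tris:
        raise StlParseError(f"{path}: ASCII STL contains no facets")
    return np.array(tris, dtype=float).reshape(-1, 3, 3)


def _parse_binary(raw: bytes, path: Path) -> np.ndarray:
    if len(raw) < 84:
        raise StlParseError(f"{path}: binary STL truncated in 84-byte header (byte {len(raw)})")
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * count
    if len(raw) < expected:
        raise StlParseError(
            f"{path}: binary STL declares {count} facets but ends at byte {len(raw)} "
            f"(expected {expected})"
        )
    body = np.frombuffer(raw, dtype=np.uint8, count=50 * count, offset=84)
    records = body.reshape(count, 50)[:, :48].copy().view("<f4").reshape(count, 12)
    return records[:, 3:12].astype(float).reshape(-1, 3, 3)


# ---------------------------------------------------------------------------
# STL writing
# ---------------------------------------------------------------------------

def write_stl(mesh: TriangleMesh, path: str | Path, dialect: str = "ascii") -> None:
    """Write ``mesh`` to STL; normals are recomputed from CCW winding."""
    if dialect not in ("ascii", "binary"):
        raise ValueError(f"dialect must be 'ascii' or 'binary', got {dialect!r}")
    mesh.validate()
    path = Path(path)
    tris = mesh.triangles
    normals = mesh.face_normals()
    if dialect == "ascii":
        lines = ["solid psiplate"]
        for n, t in zip(normals, tris):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid psiplate")
        path.write_text("\n".join(lines) + "\n")
    else:
        m = len(tris)
        rec = np.zeros(m, dtype=np.dtype([("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]))
        rec["n"] = normals.astype("<f4")
        rec["v"] = tris.astype("<f4")
        header = b"psiplate binary STL".ljust(80, b" ")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", m))
            fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def _edges(faces: np.ndarray) -> np.ndarray:
    """Directed edges (3m, 2) in winding order."""
    return np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


def diagnose(mesh: TriangleMesh) -> MeshDiagnostics:
    """Topology + edge statistics.  Never raises on bad meshes.

    Watertight: every undirected edge borders exactly two faces.
    Consistent orientation: no directed edge is traversed twice.
    Genus is reported from Euler's formula and is only meaningful when the
    surface is closed and consistently oriented.
    """
    faces = mesh.faces
    if len(faces) == 0:
        return MeshDiagnostics(False, False, 0, 0, 0, np.nan, np.nan, np.nan)
    directed = _edges(faces)
    undirected = np.sort(directed, axis=1)
    uniq, counts = np.unique(undirected, axis=0, return_counts=True)
    watertight = bool((counts == 2).all())
    _, dir_counts = np.unique(directed, axis=0, return_counts=True)
    oriented = bool((dir_counts == 1).all())
    n_v = len(np.unique(faces))
    n_e = len(uniq)
    n_f = len(faces)
    chi = n_v - n_e + n_f
    genus = (2 - chi) // 2
    lengths = np.linalg.norm(mesh.vertices[uniq[:, 0]] - mesh.vertices[uniq[:, 1]], axis=1)
    return MeshDiagnostics(
        is_watertight=watertight,
        is_consistently_oriented=oriented,
        euler_characteristic=int(chi),
        genus=int(genus),
        triangle_count=int(n_f),
        min_edge=float(lengths.min()),
        max_edge=float(lengths.max()),
        mean_edge=float(lengths.mean()),
    )
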