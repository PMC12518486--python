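"""Triangle-mesh container, file I/O, and elementary mesh operations.

The mesh is the universal geometry carrier of the package: segmented bone
surfaces, synthetic radii, model means and completions are all
:class:`TriangleMesh` instances.  Coordinates are millimetres throughout.

Reading goes through :mod:`trimesh` (PLY / STL / OBJ, ASCII and binary).
Writing is done by this module directly so vertex coordinates are stored in
double precision; binary STL is the one dialect that is float32 by format
definition.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .exceptions import MeshFormatError, ValidationError

_FORMATS = ("ply", "stl", "obj")


@dataclass
class TriangleMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    faces : (m, 3) int array
        Vertex-index triples, counter-clockwise when seen from outside.
    vertex_scalars : (n,) float array, optional
        Per-vertex scalar field (used for distance heatmaps).
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_scalars: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertex_scalars is not None:
            self.vertex_scalars = np.asarray(self.vertex_scalars, dtype=np.float64)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be an (m, 3) array")
        if not np.isfinite(self.vertices).all():
            raise MeshFormatError("non-finite vertex coordinate")
        if len(self.faces):
            lo, hi = self.faces.min(), self.faces.max()
            if lo < 0 or hi >= len(self.vertices):
                bad = int(np.flatnonzero((self.faces < 0).any(axis=1)
                                         | (self.faces >= len(self.vertices)).any(axis=1))[0])
                raise MeshFormatError(
                    f"face {bad} references vertex index outside [0, {len(self.vertices)})")
            f = self.faces
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
                bad = int(np.flatnonzero((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2])
                                         | (f[:, 0] == f[:, 2]))[0])
                raise MeshFormatError(f"face {bad} references the same vertex twice")
        if self.vertex_scalars is not None and len(self.vertex_scalars) != len(self.vertices):
            raise MeshFormatError("vertex_scalars length must equal vertex count")

    # -- basic properties ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of (min, max) corner of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def bbox_diagonal(self) -> float:
        lo, hi = self.bounds
        return float(np.linalg.norm(hi - lo))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(),
            None if self.vertex_scalars is None else self.vertex_scalars.copy())

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def signed_volume(self) -> float:
        """Signed enclosed volume by the divergence theorem (mm^3).

        Positive for a closed, outward-oriented surface.
        """
        t = self.triangles()
        return float(np.einsum("ij,ij->i", t[:, 0],
                               np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def is_closed_manifold(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        e = np.sort(np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                                    self.faces[:, [2, 0]]]), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def as_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def __eq__(self, other: object) -> bool:  # bitwise equality, used in tests
        if not isinstance(other, TriangleMesh):
            return NotImplemented
        return (self.vertices.shape == other.vertices.shape
                and self.faces.shape == other.faces.shape
                and (self.vertices == other.vertices).all()
                and (self.faces == other.faces).all())


@dataclass
class VertexSubset:
    """A sorted, unique, non-empty set of vertex indices on one mesh."""

    mesh: TriangleMesh
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        if idx.size == 0:
            raise ValidationError("vertex subset is empty")
        if idx[0] < 0 or idx[-1] >= self.mesh.n_vertices:
            raise ValidationError("vertex subset index out of range")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    def positions(self) -> np.ndarray:
        return self.mesh.vertices[self.indices]

    def mask(self) -> np.ndarray:
        m = np.zeros(self.mesh.n_vertices, dtype=bool)
        m[self.indices] = True
        return m


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValidationError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def _weld_exact(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # exact coordinate match: welding is deterministic and tolerance-free
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    return uniq, inverse[faces]


def read_mesh(path: str | Path, fmt: str | None = None) -> TriangleMesh:
    """Read a PLY, STL or OBJ surface mesh.

    STL input (a triangle soup by definition) is vertex-welded on exact
    coordinate equality.  A PLY float ``quality`` vertex property, when
    present, is loaded into :attr:`TriangleMesh.vertex_scalars`.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if not path.exists():
        raise OSError(f"mesh file not found: {path}")
    try:
        loaded = _trimesh.load(str(path), file_type=fmt, process=False,
                               force="mesh", validate=False)
    except OSError:
        raise
    except MeshFormatError:
        raise
    except Exception as exc:  # trimesh raises a zoo of parse errors
        raise MeshFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    scalars = None
    if fmt == "ply":
        raw = loaded.metadata.get("_ply_raw", {})
        vert = raw.get("vertex", {})
        data = vert.get("data") if isinstance(vert, dict) else None
        if data is not None:
            try:
                if isinstance(data, dict) and "quality" in data:
                    scalars = np.asarray(data["quality"], dtype=np.float64).ravel()
                elif getattr(data, "dtype", None) is not None and \
                        "quality" in (data.dtype.names or ()):
                    scalars = np.asarray(data["quality"], dtype=np.float64).ravel()
            except Exception:
                scalars = None
    if fmt == "stl":
        vertices, faces = _weld_exact(vertices, faces)
    return TriangleMesh(vertices, faces, scalars)


# ---------------------------------------------------------------------------
# writing (double precision, hence not delegated to trimesh)
# ---------------------------------------------------------------------------

def _write_ply(mesh: TriangleMesh, path: Path, binary: bool) -> None:
    has_q = mesh.vertex_scalars is not None
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {mesh.n_vertices}",
              "property double x", "property double y", "property double z"]
    if has_q:
        header.append("property double quality")
    header += [f"element face {mesh.n_faces}",
               "property list uchar int vertex_indices", "end_header"]
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            ncol = 4 if has_q else 3
            vdata = np.empty((mesh.n_vertices, ncol), dtype="<f8")
            vdata[:, :3] = mesh.vertices
            if has_q:
                vdata[:, 3] = mesh.vertex_scalars
            fh.write(vdata.tobytes())
            rec = np.empty(mesh.n_faces, dtype=[("n", "u1"), ("idx", "<i4", (3,))])
            rec["n"] = 3
            rec["idx"] = mesh.faces
            fh.write(rec.tobytes())
    else:
        with open(path, "w", newline="\n") as fh:
            fh.write("\n".join(header) + "\n")
            for i, v in enumerate(mesh.vertices):
                row = f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}"
                if has_q:
                    row += f" {mesh.vertex_scalars[i]:.17g}"
                fh.write(row + "\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _write_stl(mesh: TriangleMesh, path: Path, binary: bool) -> None:
    tris = mesh.triangles()
    n = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    norm = np.linalg.norm(n, axis=1)
    n = np.where(norm[:, None] > 0, n / np.maximum(norm, 1e-300)[:, None], 0.0)
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"\0" * 80)
            fh.write(struct.pack("<I", len(tris)))
            rec = np.zeros(len(tris), dtype=[("n", "<f4", (3,)), ("v", "<f4", (3, 3)),
                                             ("attr", "<u2")])
            rec["n"] = n
            rec["v"] = tris
            fh.write(rec.tobytes())
    else:
        with open(path, "w", newline="\n") as fh:
            fh.write("solid shapecomplete\n")
            for nv, t in zip(n, tris):
                fh.write(f"  facet normal {nv[0]:.17g} {nv[1]:.17g} {nv[2]:.17g}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid shapecomplete\n")


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def write_mesh(mesh: TriangleMesh, path: str | Path, fmt: str | None = None,
               binary: bool = True) -> Path:
    """Write a mesh as PLY, STL or OBJ.

    PLY and OBJ (and ASCII STL) round-trip coordinates to better than
    1e-6 mm.  Binary STL stores float32 by format definition and is the only
    lossy dialect.  A :attr:`TriangleMesh.vertex_scalars` field is written as
    a PLY ``quality`` vertex property; other formats drop it.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    mesh.validate()
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        _write_ply(mesh, path, binary)
    elif fmt == "stl":
        _write_stl(mesh, path, binary)
    else:
        _write_obj(mesh, path)
    return path


def write_scalar_csv(mesh: TriangleMesh, path: str | Path) -> Path:
    """Write the per-vertex scalar field as CSV rows (vertex_index, value)."""
    if mesh.vertex_scalars is None:
        raise ValidationError("mesh has no vertex scalar field")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex_index", "value"])
        for i, v in enumerate(mesh.vertex_scalars):
            w.writerow([i, repr(float(v))])
    return path


def read_scalar_csv(path: str | Path) -> np.ndarray:
    """Read a (vertex_index, value) CSV back into a dense scalar array."""
    idx, val = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            idx.append(int(row["vertex_index"]))
            val.append(float(row["value"]))
    out = np.full(max(idx) + 1, np.nan)
    out[np.asarray(idx)] = val
    return out


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def mirror_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """Mirror across the X=0 plane, reversing face winding.

    Left radii are mirrored into right-sided geometry before any modelling;
    the mirror plane is a fixed convention because rigid alignment follows
    anyway.  The operation is an exact involution.
    """
    v = mesh.vertices.copy()
    v[:, 0] = -v[:, 0]
    f = mesh.faces[:, [0, 2, 1]].copy()
    return TriangleMesh(v, f, None if mesh.vertex_scalars is None
                        else mesh.vertex_scalars.copy())


def cut_by_length_fraction(mesh: TriangleMesh, fraction: float,
                           axis: int = 1) -> tuple[VertexSubset, VertexSubset]:
    """Partition vertices at a fraction of the mesh's extent along an axis.

    With the canonical anatomical frame (long axis = Y, ``axis=1``) and
    ``fraction=0.88`` this yields the proximal 88% and distal 12% of a
    radius.  Returns ``(proximal, distal)``; vertices exactly at the cut
    plane are proximal.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    y = mesh.vertices[:, axis]
    cut = y.min() + fraction * (y.max() - y.min())
    prox = np.flatnonzero(y <= cut)
    dist = np.flatnonzero(y > cut)
    if dist.size == 0:
        # degenerate only when all coordinates equal; fraction<1 guarantees
        # the max-coordinate vertex is distal otherwise
        raise ValidationError("distal subset is empty (flat mesh along axis)")
    return VertexSubset(mesh, prox), VertexSubset(mesh, dist)
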