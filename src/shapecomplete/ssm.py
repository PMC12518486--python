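"""Statistical shape model: Procrustes alignment, PCA, persistence.

The model is the usual linear-Gaussian point-distribution model: a mean
shape vector (3 coordinates per reference vertex, mm) plus an orthonormal
eigenbasis of the sample covariance, components ranked by decreasing
eigenvalue.  Alignment is rigid-only — no Procrustes scaling — because
absolute size in mm is clinically meaningful (length error is one of the
evaluated degrees of freedom).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .correspondence import RegistrationSchedule, nonrigid_register
from .exceptions import ModelIntegrityError, TopologyError, ValidationError
from .geometry import apply_rigid, kabsch
from .mesh import TriangleMesh

_FILE_VERSION = 1


def _same_topology(a: TriangleMesh, b: TriangleMesh) -> bool:
    return (a.faces.shape == b.faces.shape and (a.faces == b.faces).all()
            and a.n_vertices == b.n_vertices)


@dataclass
class ShapeModel:
    """Mean shape + orthonormal PCA basis on a fixed reference topology.

    ``mean`` has length 3*n_vertices (mm); ``basis`` is (3*n_vertices, K)
    with orthonormal columns; ``eigenvalues`` (mm^2) are non-negative and
    non-increasing, K <= n_training - 1 for a PCA-built model.
    """

    reference: TriangleMesh
    mean: np.ndarray
    eigenvalues: np.ndarray
    basis: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64).ravel()
        self.basis = np.asarray(self.basis, dtype=np.float64)
        n3 = 3 * self.reference.n_vertices
        if self.mean.shape != (n3,):
            raise ValidationError("mean length must be 3 * n_vertices")
        if self.basis.shape != (n3, len(self.eigenvalues)):
            raise ValidationError("basis shape must be (3*n_vertices, K)")
        if (self.eigenvalues < -1e-12).any():
            raise ValidationError("negative eigenvalue")
        if (np.diff(self.eigenvalues) > 1e-9 * max(self.eigenvalues[0], 1.0)).any() \
                if len(self.eigenvalues) else False:
            raise ValidationError("eigenvalues must be non-increasing")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValidationError("basis columns are not orthonormal")

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_vertices(self) -> int:
        return self.reference.n_vertices

    def mean_mesh(self) -> TriangleMesh:
        return TriangleMesh(self.mean.reshape(-1, 3), self.reference.faces.copy())

    # -- generative interface -------------------------------------------
    def sample_shape(self, coefficients: np.ndarray | None = None,
                     seed: int | None = None) -> TriangleMesh:
        """shape = mean + sum_k c_k sqrt(lambda_k) basis_k.

        With ``coefficients=None`` standard-normal coefficients are drawn
        from ``seed`` (required).  All-zero coefficients give exactly the
        mean shape.
        """
        if coefficients is None:
            if seed is None:
                raise ValidationError("sample_shape needs coefficients or a seed")
            coefficients = np.random.default_rng(seed).standard_normal(self.n_components)
        c = np.asarray(coefficients, dtype=np.float64).ravel()
        if len(c) > self.n_components:
            raise ValidationError(
                f"{len(c)} coefficients but model has {self.n_components} components")
        full = np.zeros(self.n_components)
        full[:len(c)] = c
        v = self.mean + self.basis @ (np.sqrt(self.eigenvalues) * full)
        return TriangleMesh(v.reshape(-1, 3), self.reference.faces.copy())

    def project(self, shape: TriangleMesh | np.ndarray) -> np.ndarray:
        """Coefficients c_k = basis_k^T (shape - mean) / sqrt(lambda_k)."""
        if isinstance(shape, TriangleMesh):
            if not _same_topology(shape, self.reference):
                raise TopologyError("shape topology does not match the model reference")
            x = shape.vertices.ravel()
        else:
            x = np.asarray(shape, dtype=np.float64).ravel()
            if x.shape != self.mean.shape:
                raise TopologyError("shape vector length does not match the model")
        with np.errstate(divide="ignore"):
            inv_sqrt = np.where(self.eigenvalues > 0,
                                1.0 / np.sqrt(np.maximum(self.eigenvalues, 1e-300)), 0.0)
        return (self.basis.T @ (x - self.mean)) * inv_sqrt

    def reconstruct(self, coefficients: np.ndarray) -> TriangleMesh:
        return self.sample_shape(coefficients=coefficients)

    # -- persistence ----------------------------------------------------
    def _checksum(self) -> str:
        h = hashlib.sha256()
        for a in (self.reference.vertices, self.reference.faces, self.mean,
                  self.eigenvalues, self.basis):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = _FILE_VERSION
            f.attrs["metadata"] = json.dumps(self.metadata, sort_keys=True)
            f.attrs["checksum"] = self._checksum()
            f.create_dataset("reference_vertices", data=self.reference.vertices)
            f.create_dataset("faces", data=self.reference.faces)
            f.create_dataset("mean", data=self.mean)
            f.create_dataset("eigenvalues", data=self.eigenvalues)
            f.create_dataset("basis", data=self.basis)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        path = Path(path)
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != _FILE_VERSION:
                raise ModelIntegrityError(
                    f"unsupported model file version {version} (expected {_FILE_VERSION})")
            model = cls(
                reference=TriangleMesh(f["reference_vertices"][...], f["faces"][...]),
                mean=f["mean"][...], eigenvalues=f["eigenvalues"][...],
                basis=f["basis"][...],
                metadata=json.loads(f.attrs.get("metadata", "{}")))
            stored = str(f.attrs.get("checksum", ""))
        if stored != model._checksum():
            raise ModelIntegrityError(f"checksum mismatch in {path}: file corrupted")
        return model


# ---------------------------------------------------------------------------
# alignment and model building
# ---------------------------------------------------------------------------

def gpa(meshes: list[TriangleMesh], max_iter: int = 100, tol_mm: float = 1e-8
        ) -> tuple[list[TriangleMesh], np.ndarray]:
    """Generalized Procrustes analysis, rigid-only (size retained).

    Iteratively aligns every corresponded mesh to the evolving mean and
    recomputes the mean; the summed squared distance to the mean is
    non-increasing.  Returns the aligned meshes and the mean shape vector.
    """
    if len(meshes) < 2:
        raise ValidationError("GPA needs at least 2 meshes")
    first = meshes[0]
    for m in meshes[1:]:
        if not _same_topology(m, first):
            raise TopologyError("GPA requires meshes sharing one topology")
    pts = [m.vertices.copy() for m in meshes]
    mean = np.mean(pts, axis=0)
    for _ in range(max_iter):
        for i, p in enumerate(pts):
            R, t = kabsch(p, mean)
            pts[i] = apply_rigid(R, t, p)
        new_mean = np.mean(pts, axis=0)
        if np.sqrt(((new_mean - mean) ** 2).sum(axis=1).mean()) < tol_mm:
            mean = new_mean
            break
        mean = new_mean
    aligned = [TriangleMesh(p, first.faces.copy()) for p in pts]
    return aligned, mean.ravel()


def build_ssm(aligned_meshes: list[TriangleMesh],
              reference: TriangleMesh | None = None,
              metadata: dict | None = None) -> ShapeModel:
    """PCA shape model from aligned, corresponded meshes.

    Eigen-decomposition of the sample covariance (divisor n-1) via SVD of
    the centred data matrix; components with eigenvalue below 1e-12 of the
    leading one are discarded, so generic-position data keeps exactly n-1.
    """
    n = len(aligned_meshes)
    if n < 2:
        raise ValidationError("need at least 2 shapes to build a model")
    first = aligned_meshes[0]
    for m in aligned_meshes[1:]:
        if not _same_topology(m, first):
            raise TopologyError("model building requires one shared topology")
    X = np.stack([m.vertices.ravel() for m in aligned_meshes])
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s ** 2 / (n - 1)
    keep = lam > (lam[0] if len(lam) else 0.0) * 1e-12
    lam, Vt = lam[keep], Vt[keep]
    ref = reference if reference is not None else first
    if not _same_topology(ref, first):
        raise TopologyError("reference topology must match the aligned meshes")
    md = {"n_training": n, "build": "pca"}
    md.update(metadata or {})
    return ShapeModel(TriangleMesh(mean.reshape(-1, 3), ref.faces.copy()),
                      mean, lam, Vt.T, md)


def _landmark_indices_on(reference: TriangleMesh, positions: np.ndarray
                         ) -> np.ndarray:
    """Nearest reference vertex for each landmark position."""
    from scipy.spatial import cKDTree
    return cKDTree(reference.vertices).query(np.atleast_2d(positions))[1]


def correspond_all(meshes: list[TriangleMesh], reference: TriangleMesh,
                   schedule: RegistrationSchedule | None = None,
                   seed: int = 0,
                   reference_landmarks: np.ndarray | None = None,
                   mesh_landmarks: list[np.ndarray] | None = None
                   ) -> list[TriangleMesh]:
    """Nonrigidly register the reference onto every mesh.

    Meshes already sharing the reference topology are taken as corresponded
    as-is.  ``reference_landmarks`` are landmark positions on the reference
    (mapped to its nearest vertices); ``mesh_landmarks`` the matching
    positions on each mesh — when given they anchor the registration.
    """
    lm_idx = None
    if reference_landmarks is not None and mesh_landmarks is not None:
        lm_idx = _landmark_indices_on(reference, reference_landmarks)
    out = []
    for i, m in enumerate(meshes):
        if _same_topology(m, reference):
            out.append(m)
        else:
            lms = None if lm_idx is None else (lm_idx, mesh_landmarks[i])
            out.append(nonrigid_register(m, reference, schedule,
                                         seed=seed + i,
                                         landmarks=lms).corresponded())
    return out


def two_pass_build(meshes: list[TriangleMesh], initial_reference: TriangleMesh,
                   schedule: RegistrationSchedule | None = None,
                   seed: int = 0, return_aligned: bool = False,
                   reference_landmarks: np.ndarray | None = None,
                   mesh_landmarks: list[np.ndarray] | None = None):
    """Build the SSM twice, re-referenced to the first-pass mean.

    Pass 1 registers every training mesh to ``initial_reference``, aligns
    (GPA) and runs PCA.  Pass 2 repeats correspondence, GPA and PCA with
    the pass-1 mean shape as the reference, removing the bias of an
    arbitrary starting reference.  (Meshes that already share the current
    reference topology are corresponded by construction and used as-is.)
    Returns the pass-2 model.
    """
    corresponded = correspond_all(meshes, initial_reference, schedule, seed,
                                  reference_landmarks, mesh_landmarks)
    aligned, mean = gpa(corresponded)
    pass1 = build_ssm(aligned, metadata={"pass": 1})
    mean_mesh = pass1.mean_mesh()
    # the pass-1 reference's landmark vertices keep their anatomical
    # meaning on the pass-1 mean (same topology carrier)
    mean_landmarks = None
    if reference_landmarks is not None:
        idx = _landmark_indices_on(initial_reference, reference_landmarks)
        mean_landmarks = mean_mesh.vertices[idx]
    corresponded2 = correspond_all(meshes, mean_mesh, schedule,
                                   seed + 10_000, mean_landmarks,
                                   mesh_landmarks)
    aligned2, _ = gpa(corresponded2)
    model = build_ssm(aligned2, metadata={"pass": 2, "seed": seed,
                                          "two_pass": True})
    if return_aligned:
        return model, aligned2
    return model
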