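"""Anatomical coordinate frame of the radius.

The canonical frame places the origin at the center of the radial head,
runs the Y axis from there to the midpoint of the central ridge of the
distal radius, points Z toward the middle of the sigmoid notch, and takes
X = Y x Z, pointing dorsally.  All modelling happens in this frame; a
secondary origin at the distal segment's surface centroid supports the
clinical 6-DOF error decomposition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DegenerateFrameError, ValidationError
from .mesh import TriangleMesh, cut_by_length_fraction

_LANDMARK_NAMES = ("head_center", "ridge_midpoint", "notch_point")


@dataclass(frozen=True)
class LandmarkSet:
    """The three frame-defining landmarks (mm), as picked by the user."""

    head_center: np.ndarray
    ridge_midpoint: np.ndarray
    notch_point: np.ndarray

    def __post_init__(self) -> None:
        for name in _LANDMARK_NAMES:
            v = np.asarray(getattr(self, name), dtype=np.float64).reshape(3)
            object.__setattr__(self, name, v)

    def as_array(self) -> np.ndarray:
        return np.vstack([self.head_center, self.ridge_midpoint, self.notch_point])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "LandmarkSet":
        a = self.as_array() @ np.asarray(R).T + np.asarray(t)
        return LandmarkSet(a[0], a[1], a[2])


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin (radial head center) plus a right-handed rotation.

    ``rotation`` columns are the frame's X, Y, Z axes expressed in world
    coordinates; orthonormal with determinant +1.
    """

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=np.float64).reshape(3))
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise DegenerateFrameError("frame rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise DegenerateFrameError("frame rotation is left-handed")
        object.__setattr__(self, "rotation", R)

    @property
    def x_axis(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.rotation[:, 2]

    @classmethod
    def identity(cls) -> "AnatomicalFrame":
        return cls(np.zeros(3), np.eye(3))

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World -> frame coordinates: v -> R^T (v - origin)."""
        return (np.asarray(points, dtype=np.float64) - self.origin) @ self.rotation

    def from_frame(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.origin


def build_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Construct the canonical frame from the three landmarks.

    Y is the unit long-axis direction (head -> ridge midpoint); Z is the
    component of head -> notch orthogonal to Y; X = Y x Z.  Equivariant
    under rigid motion of the landmarks.
    """
    y = landmarks.ridge_midpoint - landmarks.head_center
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise DegenerateFrameError("head_center and ridge_midpoint coincide")
    y = y / ny
    z = landmarks.notch_point - landmarks.head_center
    z = z - (z @ y) * y
    nz = np.linalg.norm(z)
    if nz < 1e-9 * max(1.0, np.linalg.norm(landmarks.notch_point - landmarks.head_center)):
        raise DegenerateFrameError("notch_point is collinear with the long axis")
    z = z / nz
    x = np.cross(y, z)
    R = np.column_stack([x, y, z])
    return AnatomicalFrame(landmarks.head_center, R)


def canonicalize(mesh: TriangleMesh, frame: AnatomicalFrame) -> TriangleMesh:
    """Express a mesh in the anatomical frame (a rigid map, hence isometric)."""
    return TriangleMesh(frame.to_frame(mesh.vertices), mesh.faces.copy(),
                        None if mesh.vertex_scalars is None
                        else mesh.vertex_scalars.copy())


def distal_origin(mesh: TriangleMesh, fraction: float = 0.12) -> np.ndarray:
    """Surface centroid of the distal segment (the evaluation origin).

    Area-weighted centroid of the triangles whose three vertices all lie in
    the distal ``fraction`` of the canonical mesh.  A surface (not volume)
    centroid is used so open cut segments are well-defined.
    """
    _, dist = cut_by_length_fraction(mesh, 1.0 - fraction)
    mask = dist.mask()
    fully = mask[mesh.faces].all(axis=1)
    if not fully.any():
        raise ValidationError("no triangle lies fully within the distal segment")
    tri = mesh.vertices[mesh.faces[fully]]
    area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    centroids = tri.mean(axis=1)
    total = area.sum()
    if total <= 0:
        raise ValidationError("distal segment has zero surface area")
    return (area[:, None] * centroids).sum(axis=0) / total


def read_landmarks_csv(path: str | Path) -> LandmarkSet:
    """Read a landmarks CSV with rows ``name,x,y,z`` (mm)."""
    found: dict[str, np.ndarray] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("name", ""):
                continue
            name = row[0].strip()
            if name in _LANDMARK_NAMES:
                found[name] = np.array([float(v) for v in row[1:4]])
    missing = [n for n in _LANDMARK_NAMES if n not in found]
    if missing:
        raise ValidationError(f"landmarks file {path} missing {missing}")
    return LandmarkSet(**found)


def write_landmarks_csv(landmarks: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x", "y", "z"])
        for name in _LANDMARK_NAMES:
            p = getattr(landmarks, name)
            w.writerow([name, repr(float(p[0])), repr(float(p[1])),
                        repr(float(p[2]))])
    return path
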