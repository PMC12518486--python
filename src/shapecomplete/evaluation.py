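"""Model quality metrics: accuracy, compactness, generalization, specificity.

Accuracy is the one-sided mean point-to-surface distance of a predicted
mesh against its reference (each predicted vertex to the closest point of
the reference surface).  Compactness is the cumulative eigenvalue fraction
per component count.  Generalization tracks reconstruction RMSE of a
held-out shape as the training set grows.  Specificity asks whether shapes
sampled from the model look like real (test) shapes.  All seeded
procedures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .geometry import SurfaceQuery, surface_distance
from .mesh import TriangleMesh
from .ssm import ShapeModel, build_ssm


def accuracy(predicted: TriangleMesh, reference: TriangleMesh,
             symmetric: bool = False) -> float:
    """Mean surface distance in mm (one-sided, predicted -> reference).

    ``symmetric=True`` averages both directions instead.
    """
    d1 = surface_distance(predicted.vertices, reference)
    if not symmetric:
        return float(d1.mean())
    d2 = surface_distance(reference.vertices, predicted)
    return float(0.5 * (d1.mean() + d2.mean()))


def hausdorff_max(a: TriangleMesh, b: TriangleMesh) -> float:
    """Symmetric Hausdorff distance over vertex samples (mm)."""
    d1 = surface_distance(a.vertices, b)
    d2 = surface_distance(b.vertices, a)
    return float(max(d1.max(), d2.max()))


def heatmap(predicted: TriangleMesh, reference: TriangleMesh) -> TriangleMesh:
    """Per-vertex distance field on the predicted mesh (for PLY export)."""
    d = surface_distance(predicted.vertices, reference)
    return TriangleMesh(predicted.vertices.copy(), predicted.faces.copy(), d)


def compactness(model: ShapeModel) -> np.ndarray:
    """Cumulative variance fraction per retained component count.

    Non-decreasing curve ending at 1.
    """
    lam = model.eigenvalues
    if lam.sum() <= 0:
        raise ValidationError("model has no variance")
    return np.cumsum(lam) / lam.sum()


def n_components_for(model: ShapeModel, threshold: float = 0.95) -> int:
    """Smallest component count whose cumulative variance reaches threshold."""
    curve = compactness(model)
    return int(np.searchsorted(curve, threshold - 1e-12) + 1)


def generalization_curve(corresponded_shapes: list[TriangleMesh],
                         heldout_shape: TriangleMesh,
                         sizes: list[int] | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Projection RMSE of a held-out shape vs number of training shapes.

    The training order is one fixed seed-shuffled permutation; for each
    size ``n`` a PCA model is built on the first ``n`` shapes and the
    held-out shape is orthogonally projected onto its subspace.  RMSE is
    the root mean squared per-vertex residual distance (mm).
    """
    n_total = len(corresponded_shapes)
    if sizes is None:
        sizes = list(range(2, n_total + 1))
    if min(sizes) < 2 or max(sizes) > n_total:
        raise ValidationError("sizes must lie in [2, n_shapes]")
    order = np.random.default_rng(seed).permutation(n_total)
    shapes = [corresponded_shapes[i] for i in order]
    rows = []
    for n in sizes:
        model = build_ssm(shapes[:n])
        rec = model.reconstruct(model.project(heldout_shape))
        res = heldout_shape.vertices - rec.vertices
        rmse = float(np.sqrt((res ** 2).sum(axis=1).mean()))
        rows.append({"n_training": int(n), "rmse_mm": rmse})
    return pd.DataFrame(rows)


def specificity(model: ShapeModel, test_meshes: list[TriangleMesh],
                n_samples: int = 10, seed: int = 0,
                mode: str = "sample") -> pd.DataFrame:
    """Realism of model-generated shapes against the test set.

    ``mode="sample"`` draws ``n_samples`` shapes from the model with
    standard-normal coefficients; ``mode="reconstruct"`` instead projects
    each test mesh into the model and evaluates its reconstruction.  Each
    generated shape is scored by accuracy against its nearest test mesh
    (the one minimising accuracy) and the symmetric Hausdorff distance to
    that mesh.
    """
    if not test_meshes:
        raise ValidationError("test set is empty")
    if mode not in ("sample", "reconstruct"):
        raise ValidationError("mode must be 'sample' or 'reconstruct'")
    queries = [SurfaceQuery(t) for t in test_meshes]
    rng = np.random.default_rng(seed)
    if mode == "sample":
        generated = [model.sample_shape(
            coefficients=rng.standard_normal(model.n_components))
            for _ in range(n_samples)]
    else:
        generated = [model.reconstruct(model.project(t)) for t in test_meshes]
    rows = []
    for i, g in enumerate(generated):
        dists = [float(q.query(g.vertices)[1].mean()) for q in queries]
        nearest = int(np.argmin(dists))
        rows.append({"sample": i, "nearest_test": nearest,
                     "accuracy_mm": dists[nearest],
                     "hausdorff_mm": hausdorff_max(g, test_meshes[nearest])})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Bundle of the four model-quality metrics for a test run."""

    per_case_accuracy_mm: list[float]
    per_case_hausdorff_mm: list[float]
    compactness_curve: np.ndarray
    n_components_95: int
    generalization: pd.DataFrame | None = None
    specificity: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.compactness_curve, dtype=np.float64)
        if (np.diff(c) < -1e-12).any() or abs(c[-1] - 1.0) > 1e-9:
            raise ValidationError("compactness curve must be non-decreasing, ending at 1")
        if any(v < 0 for v in self.per_case_accuracy_mm + self.per_case_hausdorff_mm):
            raise ValidationError("distances must be non-negative")

    def to_dict(self) -> dict:
        out = {
            "per_case_accuracy_mm": [float(v) for v in self.per_case_accuracy_mm],
            "per_case_hausdorff_mm": [float(v) for v in self.per_case_hausdorff_mm],
            "mean_accuracy_mm": float(np.mean(self.per_case_accuracy_mm)),
            "max_hausdorff_mm": float(np.max(self.per_case_hausdorff_mm)),
            "compactness_curve": [float(v) for v in self.compactness_curve],
            "n_components_95": int(self.n_components_95),
        }
        if self.generalization is not None:
            out["generalization"] = self.generalization.to_dict("records")
        if self.specificity is not None:
            out["specificity"] = self.specificity.to_dict("records")
        return out
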