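"""User-facing modelling objects, in the Model -> fit() -> Results idiom.

:class:`ShapeCompletionModel` holds the training data (a corresponded or
raw mesh population plus a reference) and the build configuration;
``fit()`` runs correspondence, Procrustes alignment, PCA and the kernel
augmentation and returns a :class:`ShapeCompletionResults` carrying the
fitted statistical shape model, the augmented completion model, diagnostics
and the prediction/evaluation methods.
"""

from __future__ import annotations

from io import StringIO

import numpy as np
import pandas as pd

from .completion import (CompletionResult, KernelParams, augment_model,
                         complete, grid_search)
from .correspondence import RegistrationSchedule
from .evaluation import (accuracy, compactness, generalization_curve,
                         hausdorff_max, n_components_for, specificity)
from .exceptions import ValidationError
from .clinical import SixDofError, clinical_error
from .mesh import TriangleMesh
from .ssm import ShapeModel, build_ssm, correspond_all, gpa, two_pass_build
from .synthetic import SyntheticPopulation


class ShapeCompletionModel:
    """A shape-completion model specification, prior to fitting.

    Parameters
    ----------
    meshes : list of TriangleMesh
        Training meshes in the canonical anatomical frame.  They may share
        one topology (already corresponded) or not (correspondence is then
        established against ``reference``).
    reference : TriangleMesh, optional
        Topology carrier for the model.  Defaults to the first mesh when
        all meshes share one topology.
    schedule : RegistrationSchedule, optional
        Nonrigid registration schedule for correspondence.
    """

    def __init__(self, meshes: list[TriangleMesh],
                 reference: TriangleMesh | None = None,
                 schedule: RegistrationSchedule | None = None):
        if len(meshes) < 2:
            raise ValidationError("need at least 2 training meshes")
        self.meshes = list(meshes)
        self.reference = reference
        self.schedule = schedule or RegistrationSchedule.default()

    @classmethod
    def from_population(cls, population: SyntheticPopulation,
                        indices: list[int] | None = None,
                        **kwargs) -> "ShapeCompletionModel":
        meshes = population.meshes if indices is None else \
            [population.meshes[i] for i in indices]
        return cls(meshes, **kwargs)

    def fit(self, kernel: KernelParams | None = None, n_basis: int = 200,
            two_pass: bool = False, seed: int = 0) -> "ShapeCompletionResults":
        """Build the SSM (optionally two-pass) and augment it.

        ``kernel`` defaults to noise 20, sigma 100, scale 5 — the triple
        selected by the study's validation grid search.
        """
        kernel = kernel or KernelParams(20.0, 100.0, 5.0)
        if two_pass:
            if self.reference is None:
                raise ValidationError("two-pass build requires a reference mesh")
            ssm = two_pass_build(self.meshes, self.reference, self.schedule,
                                 seed=seed)
        else:
            ref = self.reference if self.reference is not None else self.meshes[0]
            corresponded = correspond_all(self.meshes, ref, self.schedule, seed)
            aligned, _ = gpa(corresponded)
            ssm = build_ssm(aligned, metadata={"seed": seed, "two_pass": False})
        gp = augment_model(ssm, kernel, n_basis=n_basis, seed=seed)
        return ShapeCompletionResults(self, ssm, gp, kernel, n_basis, seed)


class ShapeCompletionResults:
    """Fitted SSM + completion model with diagnostics and predictions."""

    def __init__(self, model: ShapeCompletionModel, ssm: ShapeModel,
                 gp_model: ShapeModel, kernel: KernelParams,
                 n_basis: int, seed: int):
        self.model = model
        self.ssm = ssm
        self.gp_model = gp_model
        self.kernel = kernel
        self.n_basis = n_basis
        self.seed = seed

    # -- diagnostics ----------------------------------------------------
    @property
    def eigenvalues(self) -> np.ndarray:
        return self.ssm.eigenvalues

    @property
    def n_components(self) -> int:
        return self.ssm.n_components

    def compactness(self) -> np.ndarray:
        return compactness(self.ssm)

    def n_components_for(self, threshold: float = 0.95) -> int:
        return n_components_for(self.ssm, threshold)

    def summary(self, n_show: int = 10) -> str:
        """Human-readable fit summary (eigenvalue spectrum, compactness)."""
        curve = self.compactness()
        buf = StringIO()
        buf.write("Shape completion model\n")
        buf.write("=" * 58 + "\n")
        buf.write(f"{'Training shapes:':<28}{self.ssm.metadata.get('n_training', '?')}\n")
        buf.write(f"{'Model vertices:':<28}{self.ssm.n_vertices}\n")
        buf.write(f"{'Retained components:':<28}{self.n_components}\n")
        buf.write(f"{'Components for 95% var:':<28}{self.n_components_for(0.95)}\n")
        buf.write(f"{'Kernel (noise, sigma, scale):':<28}"
                  f"({self.kernel.noise:g}, {self.kernel.sigma:g}, "
                  f"{self.kernel.scale:g})\n")
        buf.write("-" * 58 + "\n")
        buf.write(f"{'PC':>4}  {'eigenvalue (mm^2)':>18}  {'cum. variance':>14}\n")
        for k in range(min(n_show, self.n_components)):
            buf.write(f"{k + 1:>4}  {self.eigenvalues[k]:>18.4f}  "
                      f"{100 * curve[k]:>13.2f}%\n")
        if self.n_components > n_show:
            buf.write(f"{'...':>4}  ({self.n_components - n_show} more components)\n")
        buf.write("=" * 58 + "\n")
        return buf.getvalue()

    # -- prediction -----------------------------------------------------
    def complete(self, proximal_mesh: TriangleMesh, fraction: float = 0.88
                 ) -> CompletionResult:
        """Predict the full bone from a proximal segment."""
        return complete(self.ssm, proximal_mesh, self.kernel,
                        fraction=fraction, augmented=self.gp_model)

    def sample(self, seed: int | None = None,
               coefficients: np.ndarray | None = None) -> TriangleMesh:
        return self.ssm.sample_shape(coefficients=coefficients, seed=seed)

    def project(self, mesh: TriangleMesh) -> np.ndarray:
        return self.ssm.project(mesh)

    # -- evaluation -----------------------------------------------------
    def grid_search(self, validation_meshes: list[TriangleMesh],
                    grid: dict | None = None, fraction: float = 0.88,
                    score: str = "full") -> tuple[KernelParams, pd.DataFrame]:
        return grid_search(self.ssm, validation_meshes, grid=grid,
                           fraction=fraction, n_basis=self.n_basis,
                           seed=self.seed, score=score)

    def with_kernel(self, kernel: KernelParams) -> "ShapeCompletionResults":
        """Re-augment with different hyperparameters (SSM unchanged)."""
        gp = augment_model(self.ssm, kernel, n_basis=self.n_basis,
                           seed=self.seed)
        return ShapeCompletionResults(self.model, self.ssm, gp, kernel,
                                      self.n_basis, self.seed)

    def accuracy(self, predicted: TriangleMesh, reference: TriangleMesh) -> float:
        return accuracy(predicted, reference)

    def hausdorff(self, a: TriangleMesh, b: TriangleMesh) -> float:
        return hausdorff_max(a, b)

    def specificity(self, test_meshes: list[TriangleMesh],
                    n_samples: int = 10, seed: int = 0,
                    mode: str = "sample") -> pd.DataFrame:
        return specificity(self.ssm, test_meshes, n_samples, seed, mode)

    def generalization(self, heldout: TriangleMesh,
                       sizes: list[int] | None = None,
                       seed: int = 0) -> pd.DataFrame:
        corresponded = correspond_all(self.model.meshes, self.ssm.mean_mesh(),
                                      self.model.schedule, seed)
        aligned, _ = gpa(corresponded)
        return generalization_curve(aligned, heldout, sizes, seed)

    def clinical_error(self, predicted: TriangleMesh, reference: TriangleMesh,
                       fraction: float = 0.12) -> SixDofError:
        return clinical_error(predicted, reference, fraction)
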