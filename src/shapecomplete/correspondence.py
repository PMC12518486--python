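"""Rigid ICP and progressively-less-regularised nonrigid registration.

Dense correspondence with a reference mesh is what turns a pile of
independently meshed bone segmentations into shape vectors that can be
averaged and decomposed.  Registration runs in schedule steps: each step
carries a Gaussian-process deformation prior on the reference (isotropic
Gaussian kernel, low-rank via Nystrom) and alternates closest-point
matching with GP regression of the deformation.  Later steps use smaller
kernel bandwidths and more basis functions, so early steps capture global
bending and later steps local distal shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial import cKDTree

from .exceptions import ValidationError
from .geometry import SurfaceQuery, apply_rigid, kabsch
from .lowrank import lowrank_gaussian_basis
from .mesh import TriangleMesh


@dataclass(frozen=True)
class ScheduleStep:
    kernel_sigma_mm: float
    kernel_scale: float
    n_basis: int
    n_icp_iterations: int
    noise_mm: float


@dataclass(frozen=True)
class RegistrationSchedule:
    """Ordered registration steps with strictly decreasing kernel bandwidth."""

    steps: tuple[ScheduleStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError("schedule needs at least one step")
        sigmas = [s.kernel_sigma_mm for s in self.steps]
        if any(b >= a for a, b in zip(sigmas, sigmas[1:])):
            raise ValidationError(
                "kernel_sigma_mm must strictly decrease across steps "
                "(later steps deform more locally)")

    @classmethod
    def default(cls) -> "RegistrationSchedule":
        """Three steps, sigma 100/60/30 mm, growing basis, 20 iterations each."""
        return cls((ScheduleStep(100.0, 10.0, 50, 20, 1.0),
                    ScheduleStep(60.0, 10.0, 100, 20, 1.0),
                    ScheduleStep(30.0, 10.0, 200, 20, 1.0)))

    @classmethod
    def from_lists(cls, sigma, scale, n_basis, n_iter, noise) -> "RegistrationSchedule":
        return cls(tuple(ScheduleStep(*row) for row in
                         zip(sigma, scale, n_basis, n_iter, noise)))


@dataclass
class DeformationField:
    """Per-vertex displacements (mm) carrying a reference onto a target."""

    reference: TriangleMesh
    displacements: np.ndarray
    residual_mm: float = float("nan")     # final mean one-sided surface distance
    step_residuals: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.displacements, dtype=np.float64)
        if d.shape != self.reference.vertices.shape:
            raise ValidationError("displacement count must equal reference vertex count")
        if not np.isfinite(d).all():
            raise ValidationError("non-finite displacement")
        self.displacements = d

    def corresponded(self) -> TriangleMesh:
        """The deformed reference: target geometry on reference topology."""
        return TriangleMesh(self.reference.vertices + self.displacements,
                            self.reference.faces.copy())


def rigid_icp(moving: TriangleMesh | np.ndarray, fixed: TriangleMesh,
              max_iter: int = 50, tol_mm: float = 1e-6,
              init: tuple[np.ndarray, np.ndarray] | None = None
              ) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Rigid ICP of ``moving`` onto the surface of ``fixed``.

    Point-to-surface matching with a Kabsch update.  The objective is the
    RMS closest-point distance, which is non-increasing by construction
    (Kabsch minimises the sum of squares to the current footpoints and new
    footpoints can only be closer).  Returns ``(R, t, history)`` for the
    best iterate.
    """
    pts = moving.vertices if isinstance(moving, TriangleMesh) else np.asarray(moving)
    query = SurfaceQuery(fixed)
    tri = fixed.triangles()
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    fn = fn / np.maximum(np.linalg.norm(fn, axis=1), 1e-300)[:, None]
    R = np.eye(3) if init is None else np.asarray(init[0], dtype=np.float64)
    t = np.zeros(3) if init is None else np.asarray(init[1], dtype=np.float64)

    def rms_of(Rc, tc):
        d = query.query(apply_rigid(Rc, tc, pts), exact=False)[1]
        return float(np.sqrt((d ** 2).mean()))

    def point_to_plane(cur, foot, normals):
        # linearised small-rotation solve of sum ((R p + t - q) . n)^2
        A = np.hstack([np.cross(cur, normals), normals])
        b = -np.einsum("ij,ij->i", cur - foot, normals)
        try:
            x, *_ = np.linalg.lstsq(A, b, rcond=None)
        except np.linalg.LinAlgError:
            return None
        w = x[:3]
        angle = np.linalg.norm(w)
        if angle < 1e-300:
            dR = np.eye(3)
        else:
            k = w / angle
            K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            dR = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
        return dR, x[3:]

    history: list[float] = []
    best = (np.inf, R, t)
    for _ in range(max_iter):
        cur = apply_rigid(R, t, pts)
        foot, d, fi = query.query(cur, exact=False)
        rms = float(np.sqrt((d ** 2).mean()))
        history.append(rms)
        if rms < best[0]:
            best = (rms, R, t)
        if len(history) > 1 and history[-2] - rms < tol_mm:
            break
        # try a point-to-plane step (fast convergence); fall back to the
        # point-to-point Kabsch step if it does not improve the objective
        accepted = False
        step = point_to_plane(cur, foot, fn[fi])
        if step is not None:
            dR, dt = step
            R2, t2 = dR @ R, dR @ t + dt
            if rms_of(R2, t2) <= rms:
                R, t = R2, t2
                accepted = True
        if not accepted:
            dR, dt = kabsch(cur, foot)
            R2, t2 = dR @ R, dR @ t + dt
            if rms_of(R2, t2) > rms:
                break     # converged: no step improves the objective
            R, t = R2, t2
    rms = rms_of(R, t)
    if rms < best[0]:
        best = (rms, R, t)
        history.append(rms)
    return best[1], best[2], history


def nonrigid_register(target: TriangleMesh, reference: TriangleMesh,
                      schedule: RegistrationSchedule | None = None,
                      seed: int = 0, rigid_init: bool = True,
                      outlier_factor: float = 3.0,
                      outlier_floor_mm: float = 1.0,
                      max_init_rotation_deg: float = 10.0,
                      landmarks: tuple[np.ndarray, np.ndarray] | None = None,
                      landmark_weight: float = 10.0) -> DeformationField:
    """Register the reference mesh onto a target surface.

    For each schedule step a low-rank GP deformation prior is built on the
    reference (Nystrom with farthest-point landmarks, fixed seed), then
    closest-point assignment from the deformed reference to the target
    surface alternates with ridge GP regression of the displacement field.
    Correspondences farther than ``outlier_factor`` times the median
    distance are dropped for that iteration.  Steps warm-start from the best
    field found so far; a step that worsens the residual is discarded.

    ``landmarks`` — ``(reference_vertex_indices, target_positions)`` — pins
    known anatomical points with weight ``landmark_weight``.  Landmarks
    resolve the correspondence components that surface geometry leaves
    unconstrained (most importantly longitudinal stretch of the shaft,
    which closest-point matching alone cannot observe).
    """
    if schedule is None:
        schedule = RegistrationSchedule.default()
    ref_v = reference.vertices
    n = len(ref_v)
    query = SurfaceQuery(target)

    u = np.zeros_like(ref_v)
    if rigid_init:
        R, t, _ = rigid_icp(reference, target)
        # canonical-frame inputs are already rotationally aligned; a large
        # ICP rotation on a near-cylindrical bone is a spurious axial spin
        angle = np.rad2deg(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
        if angle <= max_init_rotation_deg:
            u = apply_rigid(R, t, ref_v) - ref_v

    def residual(disp: np.ndarray, exact: bool = False) -> float:
        return float(query.query(ref_v + disp, exact=exact)[1].mean())

    best_u = u.copy()
    best_res = residual(u)
    step_residuals: list[float] = []
    for si, step in enumerate(schedule.steps):
        Phi = lowrank_gaussian_basis(ref_v, step.kernel_sigma_mm,
                                     step.kernel_scale, step.n_basis,
                                     seed=seed)
        p = Phi.shape[1]
        ridge = step.noise_mm ** 2
        G0 = Phi.T @ Phi
        G_lm = np.zeros((p, p))
        rhs_lm = np.zeros((p, 3))
        if landmarks is not None:
            lm_idx = np.asarray(landmarks[0], dtype=np.int64)
            lm_disp = np.asarray(landmarks[1], dtype=np.float64) - ref_v[lm_idx]
            Phi_lm = Phi[lm_idx]
            G_lm = landmark_weight ** 2 * Phi_lm.T @ Phi_lm
            rhs_lm = landmark_weight ** 2 * Phi_lm.T @ lm_disp
        # warm start: project the current best field onto this step's basis
        C = cho_solve(cho_factor(G0 + ridge * np.eye(p)), Phi.T @ best_u)
        step_best_u, step_best_res = best_u, best_res
        tgt_v = target.vertices
        for _ in range(step.n_icp_iterations):
            disp = Phi @ C
            deformed = ref_v + disp
            foot, d, _ = query.query(deformed, exact=False)
            med = np.median(d)
            # floor keeps legitimately deformed regions when most of the
            # surface already coincides (median near zero)
            keep = d <= outlier_factor * med + outlier_floor_mm
            # symmetric matching: target vertices also pull their nearest
            # deformed-reference vertex, so stretched regions (where the
            # forward direction alone would leave the target uncovered)
            # receive correspondences too
            tree = cKDTree(deformed)
            dr, assign = tree.query(tgt_v)
            rkeep = dr <= outlier_factor * np.median(dr) + outlier_floor_mm
            cnt = np.bincount(assign[rkeep], minlength=n).astype(float)
            sums = np.zeros_like(deformed)
            np.add.at(sums, assign[rkeep], tgt_v[rkeep])
            w_f = keep.astype(float)
            y = w_f[:, None] * foot + sums
            wtot = w_f + cnt
            use = wtot > 0
            y[use] = y[use] / wtot[use, None]
            obs = y - ref_v               # displacement observations
            if use.all():
                G = G0
                rhs = Phi.T @ obs
            else:
                Phi_out = Phi[~use]
                G = G0 - Phi_out.T @ Phi_out
                rhs = Phi[use].T @ obs[use]
            C = cho_solve(cho_factor(G + G_lm + ridge * np.eye(p)),
                          rhs + rhs_lm)
            res = residual(Phi @ C)
            if res < step_best_res:
                step_best_res, step_best_u = res, Phi @ C
        if step_best_res < best_res:      # discard steps that made things worse
            best_res, best_u = step_best_res, step_best_u
        step_residuals.append(best_res)
    return DeformationField(reference, best_u, residual(best_u, exact=True),
                            step_residuals)
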