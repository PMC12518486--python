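"""Low-rank Gaussian-kernel machinery: FPS landmarks + Nystrom eigenpairs.

Both the nonrigid registration prior and the completion model's kernel
augmentation need the leading eigenpairs of an isotropic Gaussian kernel
evaluated on a few thousand reference vertices.  A Nystrom approximation on
farthest-point-sampled landmark vertices keeps that cheap; with landmarks =
all points it reduces to the dense eigendecomposition (used as the oracle
in tests).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def isotropic_kernel(x: np.ndarray, y: np.ndarray, sigma: float,
                     scale: float) -> np.ndarray:
    """k(x, x') = scale * exp(-||x - x'||^2 / sigma^2).

    No factor 2 in the denominator — sigma is the lag at which correlation
    drops to e^-1 of the amplitude ``scale``.
    """
    d2 = cdist(np.atleast_2d(x), np.atleast_2d(y), "sqeuclidean")
    return scale * np.exp(-d2 / (sigma * sigma))


def farthest_point_sampling(points: np.ndarray, n_samples: int,
                            seed: int = 0) -> np.ndarray:
    """Indices of ``n_samples`` points chosen by farthest-point traversal.

    Deterministic given the seed (which picks the starting point only).
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    n_samples = min(n_samples, n)
    rng = np.random.default_rng(seed)
    chosen = np.empty(n_samples, dtype=np.int64)
    chosen[0] = int(rng.integers(n))
    d = np.linalg.norm(points - points[chosen[0]], axis=1)
    for i in range(1, n_samples):
        chosen[i] = int(np.argmax(d))
        d = np.minimum(d, np.linalg.norm(points - points[chosen[i]], axis=1))
    return chosen


def nystrom_eigenpairs(points: np.ndarray, sigma: float, scale: float,
                       n_components: int, n_landmarks: int | None = None,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Leading eigenpairs of the kernel matrix on ``points``.

    Returns ``(eigenvalues, eigenvectors)`` with eigenvectors of unit norm
    (columns), approximating the dense kernel matrix's leading
    eigendecomposition; exact when ``n_landmarks >= len(points)``.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    if n_landmarks is None:
        n_landmarks = min(n, max(3 * n_components, n_components + 20))
    n_landmarks = min(n_landmarks, n)
    n_components = min(n_components, n_landmarks)
    idx = farthest_point_sampling(points, n_landmarks, seed)
    K_mm = isotropic_kernel(points[idx], points[idx], sigma, scale)
    w, U = np.linalg.eigh(K_mm)
    order = np.argsort(w)[::-1][:n_components]
    w, U = w[order], U[:, order]
    keep = w > max(w[0], 0.0) * 1e-12
    w, U = w[keep], U[:, keep]
    K_nm = isotropic_kernel(points, points[idx], sigma, scale)
    # out-of-sample extension, then exact rescaling to unit-norm vectors
    V = K_nm @ (U / w)
    norms = np.linalg.norm(V, axis=0)
    V = V / norms
    lam = (n / n_landmarks) * w
    if n_landmarks == n:
        lam = w
    return lam, V


def lowrank_gaussian_basis(points: np.ndarray, sigma: float, scale: float,
                           n_components: int, n_landmarks: int | None = None,
                           seed: int = 0) -> np.ndarray:
    """Scalar basis ``Phi`` with ``Phi @ Phi.T ~ K``: eigenvectors * sqrt(lam)."""
    lam, V = nystrom_eigenpairs(points, sigma, scale, n_components,
                                n_landmarks, seed)
    return V * np.sqrt(lam)
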