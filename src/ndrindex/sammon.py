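"""Sammon mapping: non-linear dimension reduction preserving local distances.

Minimizes the Sammon stress

    E = (1 / sum_{i<j} D_ij) * sum_{i<j} (D_ij - d_ij)^2 / D_ij

where ``D`` are input-space and ``d`` embedding-space Euclidean distances.
The descent starts from the PCA projection (deterministic) and takes
gradient steps with backtracking halving, so the stress is non-increasing
across accepted iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["SammonResult", "sammon"]


@dataclass(frozen=True)
class SammonResult:
    points: np.ndarray
    stress: float
    n_iter: int
    converged: bool


def _stress(D_cond: np.ndarray, Y: np.ndarray, c: float) -> float:
    d = pdist(Y)
    return float(np.sum((D_cond - d) ** 2 / D_cond) / c)


def _pca_init(X: np.ndarray, d: int) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    # deterministic thin SVD; components beyond the data rank are zero
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    Y = U[:, :d] * s[:d]
    if Y.shape[1] < d:
        Y = np.hstack([Y, np.zeros((X.shape[0], d - Y.shape[1]))])
    return Y


def sammon(
    X: np.ndarray,
    d: int = 2,
    max_iter: int = 200,
    tol: float = 1e-9,
    seed: int | None = None,
) -> SammonResult:
    """Embed the rows of ``X`` into ``d`` dimensions by Sammon's method.

    Parameters
    ----------
    X:
        ``n x p`` data matrix; rows must be pairwise distinct (zero input
        distances make the stress undefined).
    d:
        Target dimensionality.
    max_iter:
        Maximum number of accepted gradient steps.
    tol:
        Relative stress-improvement threshold declaring convergence.
    seed:
        Accepted for interface uniformity; the descent itself is
        deterministic (PCA initialization).
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    D_cond = pdist(X)
    if np.any(D_cond == 0.0):
        raise ValueError(
            "duplicate input rows (zero pairwise distance); "
            "deduplicate or jitter before Sammon mapping"
        )
    c = float(D_cond.sum())
    D = squareform(D_cond, checks=False)

    Y = _pca_init(X, d)
    E = _stress(D_cond, Y, c)
    step = 0.3
    n_iter = 0
    converged = False
    eye = np.eye(n, dtype=bool)
    D_safe = D.copy()
    D_safe[eye] = 1.0  # diagonal excluded from the ratio below

    for _ in range(max_iter):
        dy = squareform(pdist(Y), checks=False)
        dy = np.maximum(dy, 1e-12)  # coincident embedded points
        dy[eye] = 1.0  # diagonal excluded by the zero factor below
        ratio = (D - dy) / (D_safe * dy)
        ratio[eye] = 0.0
        # gradient of E wrt Y (up to the constant -2/c, absorbed in the step)
        grad = ratio.sum(axis=1)[:, None] * Y - ratio @ Y
        gnorm = np.sqrt((grad**2).sum())
        if gnorm == 0.0:
            converged = True
            break
        direction = grad / gnorm
        accepted = False
        trial = step
        for _ in range(30):
            Y_new = Y + trial * direction
            E_new = _stress(D_cond, Y_new, c)
            if E_new < E:
                accepted = True
                break
            trial /= 2.0
        if not accepted:
            converged = True
            break
        improvement = (E - E_new) / E if E > 0 else 0.0
        Y, E = Y_new, E_new
        step = min(trial * 2.0, 1.0)
        n_iter += 1
        if improvement < tol:
            converged = True
            break

    return SammonResult(points=Y, stress=E, n_iter=n_iter, converged=converged)
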