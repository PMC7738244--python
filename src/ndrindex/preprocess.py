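"""Normalization and dimension-reduction method registry.

The candidate preprocessing paths scored by the index are the Cartesian
product of the registered normalizations (matrix -> matrix) and reductions
(matrix -> low-dimensional embedding).  Built-ins cover the common
scaling-factor, log and z-score normalizations plus TMM, and PCA, t-SNE and
Sammon mapping; anything else is added through :meth:`MethodRegistry.add_normalization`
/ :meth:`MethodRegistry.add_reduction`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .core import Embedding, InvalidInputError
from .sammon import sammon

__all__ = [
    "ExpressionMatrix",
    "MethodRegistry",
    "normalize_library_size",
    "normalize_log",
    "normalize_scale",
    "tmm_factors",
    "normalize_tmm",
    "reduce_pca",
    "reduce_sammon",
    "reduce_tsne",
    "default_registry",
]

NormFn = Callable[["ExpressionMatrix"], "ExpressionMatrix"]
ReduceFn = Callable[[np.ndarray, int], Embedding]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Cells x genes non-negative expression matrix with identifiers.

    ``counts`` may hold raw counts or normalized values; rows are cells.
    """

    counts: np.ndarray
    cell_ids: tuple[str, ...] = ()
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = self.counts
        if sp.issparse(X):
            X = np.asarray(X.todense())
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise InvalidInputError(f"expression matrix must be 2-D, got {X.shape}")
        n_cells, n_genes = X.shape
        if n_cells < 2 or n_genes < 2:
            raise InvalidInputError(
                f"need >= 2 cells and >= 2 genes, got {n_cells} x {n_genes}"
            )
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("expression matrix contains non-finite values")
        if np.any(X < 0):
            raise InvalidInputError("expression matrix contains negative values")
        object.__setattr__(self, "counts", X)
        cells = tuple(self.cell_ids) or tuple(f"cell{i}" for i in range(n_cells))
        genes = tuple(self.gene_ids) or tuple(f"gene{j}" for j in range(n_genes))
        if len(cells) != n_cells:
            raise InvalidInputError(f"{len(cells)} cell ids for {n_cells} cells")
        if len(genes) != n_genes:
            raise InvalidInputError(f"{len(genes)} gene ids for {n_genes} genes")
        if len(set(cells)) != len(cells):
            raise InvalidInputError("duplicate cell ids")
        if len(set(genes)) != len(genes):
            raise InvalidInputError("duplicate gene ids")
        object.__setattr__(self, "cell_ids", cells)
        object.__setattr__(self, "gene_ids", genes)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def with_counts(self, counts: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(counts, self.cell_ids, self.gene_ids)


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

def normalize_library_size(
    X: ExpressionMatrix, target_sum: float = 1e4
) -> ExpressionMatrix:
    """Rescale each cell so its total expression equals ``target_sum``."""
    totals = X.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise InvalidInputError(
            f"cell(s) with zero total count: {[X.cell_ids[i] for i in zero[:5]]}"
        )
    return X.with_counts(X.counts * (target_sum / totals)[:, None])


def normalize_log(X: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Entrywise natural log of ``x + pseudocount``."""
    if pseudocount <= 0:
        raise InvalidInputError("pseudocount must be positive")
    return X.with_counts(np.log(X.counts + pseudocount))


def normalize_scale(X: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score (sample standard deviation, ddof=1).

    Constant genes carry no signal and are mapped to zero columns with a
    warning; the z-scored output is no longer non-negative, so it bypasses
    the non-negativity check.
    """
    mat = X.counts
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene column(s) set to zero in z-scoring",
            stacklevel=2,
        )
    sd_safe = np.where(constant, 1.0, sd)
    Z = (mat - mean) / sd_safe
    Z[:, constant] = 0.0
    out = object.__new__(ExpressionMatrix)
    object.__setattr__(out, "counts", Z)
    object.__setattr__(out, "cell_ids", X.cell_ids)
    object.__setattr__(out, "gene_ids", X.gene_ids)
    return out


def tmm_factors(
    X: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factor per cell.

    The reference cell is the one whose upper-quartile expression fraction
    is closest to the mean across cells.  For every cell, log2 expression
    ratios (M) and mean log2 abundances (A) against the reference are formed
    over genes positive in both; entries in the extreme ``trim_m`` /
    ``trim_a`` quantile tails of M / A are discarded and the factor is
    ``2 ** weighted_mean(M)`` with inverse delta-method-variance weights.
    Factors are renormalized to geometric mean 1.
    """
    counts = X.counts
    lib = counts.sum(axis=1)
    if np.any(lib == 0):
        raise InvalidInputError("cell with zero total count")
    uq = np.percentile(counts, 75, axis=1) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    r, Nr = counts[ref], lib[ref]

    factors = np.empty(X.n_cells)
    for i in range(X.n_cells):
        x, Nx = counts[i], lib[i]
        both = (x > 0) & (r > 0)
        if not both.any():
            raise InvalidInputError(
                f"cell {X.cell_ids[i]} shares no positive genes with the "
                f"reference {X.cell_ids[ref]}"
            )
        xs, rs = x[both] / Nx, r[both] / Nr
        M = np.log2(xs / rs)
        A = 0.5 * np.log2(xs * rs)
        lo_m, hi_m = np.quantile(M, [trim_m, 1.0 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1.0 - trim_a])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if not keep.any():
            keep = np.ones_like(keep)
        w = 1.0 / ((Nx - x[both]) / (Nx * x[both]) + (Nr - r[both]) / (Nr * r[both]))
        factors[i] = 2.0 ** (np.sum(M[keep] * w[keep]) / np.sum(w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def normalize_tmm(
    X: ExpressionMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> ExpressionMatrix:
    """Divide each cell by its TMM-effective library size, rescaled so the
    mean effective library size is preserved."""
    factors = tmm_factors(X, trim_m=trim_m, trim_a=trim_a)
    eff = X.counts.sum(axis=1) * factors
    return X.with_counts(X.counts / eff[:, None] * eff.mean())


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def _sign_fix(scores: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Flip each principal axis so its largest-magnitude loading is positive."""
    flip = np.array(
        [np.sign(c[np.argmax(np.abs(c))]) or 1.0 for c in components]
    )
    return scores * flip


def reduce_pca(X: np.ndarray, d: int = 2) -> Embedding:
    """Projection onto the top-``d`` principal axes of the centered matrix."""
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if not 1 <= d <= min(n, p):
        raise InvalidInputError(f"PCA dimension d={d} outside [1, min(n, p)={min(n, p)}]")
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(X)
    return Embedding(_sign_fix(scores, pca.components_))


def reduce_sammon(
    X: np.ndarray,
    d: int = 2,
    max_iter: int = 200,
    tol: float = 1e-9,
    seed: int = 0,
) -> Embedding:
    """Sammon mapping to ``d`` dimensions (PCA-initialized descent)."""
    result = sammon(X, d=d, max_iter=max_iter, tol=tol, seed=seed)
    if not result.converged:
        warnings.warn(
            f"Sammon mapping stopped after {result.n_iter} iterations at "
            f"stress {result.stress:.3g} without converging",
            stacklevel=2,
        )
    return Embedding(result.points)


def reduce_tsne(
    X: np.ndarray,
    d: int = 2,
    perplexity: float = 30.0,
    seed: int = 0,
) -> Embedding:
    """Seeded t-SNE embedding.

    High-dimensional inputs are first projected to at most 50 principal
    components (the standard pipeline) before the t-SNE optimization; the
    contract is determinism for a fixed seed, not a particular layout.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if perplexity >= n:
        raise InvalidInputError(f"perplexity {perplexity} must be < n_cells={n}")
    if X.shape[1] > 50:
        X = PCA(n_components=min(50, n), svd_solver="full").fit_transform(X)
    try:
        tsne = TSNE(
            n_components=d,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
            learning_rate="auto",
        )
        Y = tsne.fit_transform(X)
    except Exception as exc:  # pragma: no cover - backend surface
        raise RuntimeError(
            f"t-SNE backend failed (d={d}, perplexity={perplexity}, seed={seed}): {exc}"
        ) from exc
    return Embedding(np.asarray(Y, dtype=np.float64))


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass
class MethodRegistry:
    """Named normalization and reduction methods defining the combo grid.

    Every registered transform must be a pure function of its input plus the
    explicit seed it receives; names are unique per side.
    """

    normalizations: dict[str, NormFn] = field(default_factory=dict)
    reductions: dict[str, ReduceFn] = field(default_factory=dict)

    def add_normalization(self, name: str, fn: NormFn) -> None:
        if name in self.normalizations:
            raise ValueError(f"normalization {name!r} already registered")
        self.normalizations[name] = fn

    def add_reduction(self, name: str, fn: ReduceFn) -> None:
        if name in self.reductions:
            raise ValueError(f"reduction {name!r} already registered")
        self.reductions[name] = fn


def default_registry(
    d: int = 2,
    perplexity: float = 30.0,
    tmm_trim_m: float = 0.30,
    tmm_trim_a: float = 0.05,
) -> MethodRegistry:
    """The built-in 5 x 3 grid crossed with PCA, Sammon and t-SNE.

    Normalizations mirror what the field's scaling-factor pipelines hand to
    dimension reduction, which is log-scale expression:

    * ``identity`` — raw counts passthrough (negative control);
    * ``log`` — log1p of raw counts, no depth correction;
    * ``libsize`` — library-size scaling then log1p (LogNormalize-style);
    * ``tmm`` — TMM effective-library scaling then log1p (log-CPM-style);
    * ``scale`` — per-gene z-score.
    """
    reg = MethodRegistry()
    reg.add_normalization("identity", lambda X: X)
    reg.add_normalization(
        "libsize", lambda X: normalize_log(normalize_library_size(X))
    )
    reg.add_normalization("log", normalize_log)
    reg.add_normalization("scale", normalize_scale)
    reg.add_normalization(
        "tmm",
        lambda X: normalize_log(normalize_tmm(X, trim_m=tmm_trim_m, trim_a=tmm_trim_a)),
    )
    reg.add_reduction("pca", lambda X, seed: reduce_pca(X, d=d))
    reg.add_reduction("sammon", lambda X, seed: reduce_sammon(X, d=d, seed=seed))
    reg.add_reduction(
        "tsne", lambda X, seed: reduce_tsne(X, d=d, perplexity=perplexity, seed=seed)
    )
    return reg
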