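"""Synthetic fixtures: 2-D shape point sets and planted-cluster count data.

Two generators make the whole pipeline testable without downloads:

* :func:`make_shape` draws 2-D point sets (gaussian blob, square outline,
  hexagram outline, uniform box) whose overall extent is controlled by a
  single ``spread`` factor, emulating the aggregate-to-diffuse gradations
  used to probe a clustering-tendency score.
* :func:`simulate_counts` draws a cells x genes negative-binomial count
  matrix with ``k`` planted cell clusters distinguished by blocks of marker
  genes, with extra zeros injected to reach the ~90% sparsity typical of
  single-cell RNA-seq.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Embedding, InvalidInputError
from .preprocess import ExpressionMatrix

__all__ = ["ShapeSpec", "ScSimSpec", "make_shape", "simulate_counts"]

SHAPES = ("gaussian", "square", "hexagram", "random")


@dataclass(frozen=True)
class ShapeSpec:
    """A 2-D shape draw: which outline, how many points, how spread out."""

    shape: str
    n: int = 500
    spread: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise InvalidInputError(
                f"unknown shape {self.shape!r}; choose from {SHAPES}"
            )
        if self.n < 2:
            raise InvalidInputError(f"need n >= 2 points, got {self.n}")
        if not self.spread > 0:
            raise InvalidInputError("spread must be positive")


@dataclass(frozen=True)
class ScSimSpec:
    """Planted-cluster scRNA-seq count simulation parameters.

    ``base_mean`` is the negative-binomial mean of background genes,
    ``marker_mean`` the elevated mean of a cluster's own marker block,
    ``dispersion`` the NB size parameter (smaller = more overdispersed),
    ``depth_sd`` the log-scale spread of per-cell sequencing-depth factors
    (the technical variation that scaling-factor normalizations remove), and
    ``dropout_target`` the overall zero fraction to reach by injecting
    additional zeros.
    """

    n_cells: int = 500
    n_genes: int = 2000
    k_clusters: int = 4
    markers_per_cluster: int = 100
    base_mean: float = 0.5
    marker_mean: float = 8.0
    dispersion: float = 0.5
    depth_sd: float = 0.35
    dropout_target: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_clusters < 1:
            raise InvalidInputError("k_clusters must be >= 1")
        if not 0.0 <= self.dropout_target < 1.0:
            raise InvalidInputError("dropout_target must lie in [0, 1)")
        if self.k_clusters * self.markers_per_cluster > self.n_genes:
            raise InvalidInputError("marker blocks exceed the gene count")


_JITTER_FRACTION = 0.02  # outline jitter sd as a fraction of spread


def _unit_square(n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform on the perimeter of the side-2 square around 0."""
    t = rng.uniform(0.0, 4.0, size=n)
    side = np.floor(t).astype(int)
    u = 2.0 * (t - side) - 1.0
    pts = np.empty((n, 2))
    pts[side == 0] = np.column_stack([u[side == 0], np.full((side == 0).sum(), -1.0)])
    pts[side == 1] = np.column_stack([np.full((side == 1).sum(), 1.0), u[side == 1]])
    pts[side == 2] = np.column_stack([-u[side == 2], np.full((side == 2).sum(), 1.0)])
    pts[side == 3] = np.column_stack([np.full((side == 3).sum(), -1.0), -u[side == 3]])
    return pts


def _unit_hexagram(n: int) -> np.ndarray:
    """n points equally spaced along the outlines of two overlapping
    equilateral triangles (a six-pointed star of circumradius 1)."""
    angles_up = np.array([90.0, 210.0, 330.0]) * np.pi / 180.0
    angles_down = np.array([270.0, 30.0, 150.0]) * np.pi / 180.0
    vertices = [np.column_stack([np.cos(a), np.sin(a)]) for a in (angles_up, angles_down)]
    edges = []
    for tri in vertices:
        for i in range(3):
            edges.append((tri[i], tri[(i + 1) % 3]))
    per_edge = np.full(len(edges), n // len(edges))
    per_edge[: n % len(edges)] += 1
    pts = []
    for (a, b), m in zip(edges, per_edge):
        frac = (np.arange(m) + 0.5) / m
        pts.append(a + frac[:, None] * (b - a))
    return np.vstack(pts)


def make_shape(spec: ShapeSpec) -> Embedding:
    """Draw the 2-D point set described by ``spec``.

    All shapes are built in a unit frame and multiplied by ``spread`` last,
    so the output bounding box scales linearly with ``spread`` and two draws
    differing only in spread are exact rescalings of each other.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if spec.shape == "gaussian":
        unit = rng.standard_normal((n, 2))
    elif spec.shape == "random":
        unit = rng.uniform(-0.5, 0.5, size=(n, 2))
    elif spec.shape == "square":
        unit = _unit_square(n, rng) + _JITTER_FRACTION * rng.standard_normal((n, 2))
    else:  # hexagram
        unit = _unit_hexagram(n) + _JITTER_FRACTION * rng.standard_normal((n, 2))
    return Embedding(spec.spread * unit)


def simulate_counts(spec: ScSimSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Planted-cluster negative-binomial counts with injected dropout.

    Cells get uniform cluster labels; each cluster elevates its own block of
    ``markers_per_cluster`` genes from ``base_mean`` to ``marker_mean``.
    Every cell's expected expression is further multiplied by a lognormal
    sequencing-depth factor (sigma = ``depth_sd``, mean-1 normalized), the
    technical component a library-size or TMM normalization should undo.
    Counts are NB(size=dispersion, mean=mu).  If the realized zero fraction
    falls short of ``dropout_target``, entries are zeroed independently at
    the rate that closes the gap; if the matrix is already sparser, a
    warning is issued and nothing is injected.

    Returns the count matrix and the ground-truth labels.
    """
    rng = np.random.default_rng(spec.seed)
    labels = rng.integers(spec.k_clusters, size=spec.n_cells)

    mu = np.full((spec.n_cells, spec.n_genes), spec.base_mean)
    for c in range(spec.k_clusters):
        block = slice(c * spec.markers_per_cluster, (c + 1) * spec.markers_per_cluster)
        mu[labels == c, block] = spec.marker_mean
    depth = np.exp(spec.depth_sd * rng.standard_normal(spec.n_cells))
    mu *= (depth / depth.mean())[:, None]

    r = spec.dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p).astype(np.float64)

    zero_frac = float(np.mean(counts == 0))
    if zero_frac < spec.dropout_target:
        q = (spec.dropout_target - zero_frac) / (1.0 - zero_frac)
        counts[rng.random(counts.shape) < q] = 0.0
    elif zero_frac > spec.dropout_target:
        warnings.warn(
            f"matrix already sparser ({zero_frac:.3f}) than dropout_target "
            f"{spec.dropout_target}; no zeros injected",
            stacklevel=2,
        )

    X = ExpressionMatrix(
        counts,
        tuple(f"cell{i}" for i in range(spec.n_cells)),
        tuple(f"gene{j}" for j in range(spec.n_genes)),
    )
    return X, labels
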