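"""Core clustering-tendency index (NDRindex).

The index rates how aggregated a low-dimensional point set is, on a scale
where 1 means every detected point-gathering area has zero radius.  It is
computed in three steps:

1.  The *average scale* ``M / log10(n)`` where ``M`` is the lower-quartile
    pairwise Euclidean distance and ``n`` the number of points.  Two points
    closer than the average scale are considered "close".
2.  A randomized greedy aggregation: starting from one random point, the
    unassigned point nearest to the active cluster's geometric center is
    absorbed while it lies within the average scale; otherwise it founds a
    new active cluster.  This partitions the points into point-gathering
    areas.
3.  ``index = 1 - R / scale`` where ``R`` is the unweighted mean, over the
    clusters found, of each cluster's mean member-to-centroid distance.

Because only the starting point is random the index is averaged over many
repeats (100 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Embedding",
    "DistanceMatrix",
    "AverageScale",
    "AggregationResult",
    "NdrScore",
    "InvalidInputError",
    "DegenerateDataError",
    "pairwise_distances",
    "average_scale",
    "grow_clusters",
    "ndrindex_score",
]


class InvalidInputError(ValueError):
    """Raised when an input violates a structural precondition."""


class DegenerateDataError(ValueError):
    """Raised when the index is mathematically undefined for the input.

    Typical cause: at least three quarters of all point pairs coincide, so
    the lower-quartile distance M is zero and the average scale vanishes.
    Deduplicate cells or add a small jitter before scoring.
    """


@dataclass(frozen=True)
class Embedding:
    """An ``n x d`` real point set with one identifier per point."""

    points: np.ndarray
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2:
            raise InvalidInputError(f"points must be 2-D, got shape {pts.shape}")
        n, d = pts.shape
        if n < 2:
            raise InvalidInputError(f"need at least 2 points, got {n}")
        if d < 1:
            raise InvalidInputError("need at least 1 coordinate dimension")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("points contain non-finite coordinates")
        object.__setattr__(self, "points", pts)
        ids = tuple(self.ids) if len(self.ids) else tuple(f"p{i}" for i in range(n))
        if len(ids) != n:
            raise InvalidInputError(f"{len(ids)} ids for {n} points")
        object.__setattr__(self, "ids", ids)

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric Euclidean distance matrix with zero diagonal."""

    values: np.ndarray

    def condensed(self) -> np.ndarray:
        """The n(n-1)/2 unordered off-diagonal pair distances."""
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class AverageScale:
    """The "close" threshold M / log10(n)."""

    M: float
    scale: float


@dataclass(frozen=True)
class AggregationResult:
    """Outcome of one greedy aggregation pass."""

    assignments: np.ndarray  # cluster id per point, 0..K-1 in founding order
    K: int
    radii: np.ndarray  # mean member-to-final-centroid distance per cluster
    R: float  # unweighted mean of radii
    index: float  # 1 - R / scale


@dataclass(frozen=True)
class NdrScore:
    """Repeat-averaged index for one embedding."""

    mean_index: float
    repeats: int
    per_repeat: np.ndarray = field(repr=False)
    seed: int


def pairwise_distances(emb: Embedding) -> DistanceMatrix:
    """Full Euclidean distance matrix of an embedding."""
    return DistanceMatrix(squareform(pdist(emb.points), checks=False))


def average_scale(dist: DistanceMatrix, n: int | None = None) -> AverageScale:
    """Lower-quartile pair distance M divided by log10(n).

    M is the 25th percentile (linear interpolation) of the n(n-1)/2
    unordered pair distances; diagonal zeros are not pairs and are excluded.
    A zero M means the data is degenerately duplicated and the index is
    undefined, so that case raises rather than substituting an epsilon.
    """
    condensed = dist.condensed()
    if n is None:
        n = dist.values.shape[0]
    if n < 2:
        raise InvalidInputError(f"need at least 2 points, got n={n}")
    M = float(np.percentile(condensed, 25.0))
    if M <= 0.0:
        raise DegenerateDataError(
            "lower-quartile pair distance is 0 (>=75% of pairs coincide); "
            "deduplicate points or add jitter before scoring"
        )
    return AverageScale(M=M, scale=M / np.log10(n))


def grow_clusters(
    emb: Embedding,
    scale: AverageScale,
    rng: np.random.Generator,
) -> AggregationResult:
    """One randomized greedy aggregation pass.

    A random point opens the first cluster.  Repeatedly, the unassigned
    point nearest to the active cluster's geometric center (arithmetic mean
    of its members) is found; if its distance to the center is strictly
    below the average scale it is absorbed and the center updated, otherwise
    it opens a new active cluster.  Closed clusters are never revisited.
    Ties in the nearest-point search go to the lowest point index.

    Radii are computed against each cluster's *final* center.  Only the
    starting point consumes randomness; `rng` is drawn from exactly once.
    """
    if not scale.scale > 0:
        raise DegenerateDataError("average scale must be positive")
    pts = emb.points
    n = pts.shape[0]
    start = int(rng.integers(n))

    assignments = np.full(n, -1, dtype=np.intp)
    unassigned = np.ones(n, dtype=bool)
    members: list[list[int]] = [[start]]
    assignments[start] = 0
    unassigned[start] = False
    center_sum = pts[start].copy()
    center = pts[start].copy()
    active_size = 1

    while unassigned.any():
        remaining = np.flatnonzero(unassigned)
        d2 = np.einsum("ij,ij->i", pts[remaining] - center, pts[remaining] - center)
        j = int(np.argmin(d2))  # first minimum -> lowest point index
        b = int(remaining[j])
        if np.sqrt(d2[j]) < scale.scale:
            members[-1].append(int(b))
            center_sum += pts[b]
            active_size += 1
            center = center_sum / active_size
        else:
            members.append([int(b)])
            center_sum = pts[b].copy()
            center = pts[b].copy()
            active_size = 1
        assignments[b] = len(members) - 1
        unassigned[b] = False

    K = len(members)
    radii = np.empty(K)
    for k, idx in enumerate(members):
        cluster = pts[idx]
        final_center = cluster.mean(axis=0)
        radii[k] = np.sqrt(
            np.einsum("ij,ij->i", cluster - final_center, cluster - final_center)
        ).mean()
    R = float(radii.mean())
    return AggregationResult(
        assignments=assignments,
        K=K,
        radii=radii,
        R=R,
        index=1.0 - R / scale.scale,
    )


def ndrindex_score(
    emb: Embedding,
    repeats: int = 100,
    seed: int = 0,
) -> NdrScore:
    """Repeat-averaged clustering-tendency index of an embedding.

    Runs the greedy aggregation `repeats` times, each from an independently
    drawn starting point (per-repeat substreams spawned from `seed`), and
    averages the per-repeat index values.  Deterministic for fixed
    ``(emb, repeats, seed)``.
    """
    if repeats < 1:
        raise InvalidInputError(f"repeats must be >= 1, got {repeats}")
    scale = average_scale(pairwise_distances(emb), emb.n)
    streams = np.random.SeedSequence(seed).spawn(repeats)
    per_repeat = np.empty(repeats)
    for i, stream in enumerate(streams):
        result = grow_clusters(emb, scale, np.random.default_rng(stream))
        per_repeat[i] = result.index
    return NdrScore(
        mean_index=float(per_repeat.mean()),
        repeats=repeats,
        per_repeat=per_repeat,
        seed=seed,
    )
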