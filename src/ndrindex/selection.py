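"""Preprocessing-path enumeration, scoring, selection and ARI evaluation.

The workflow mirrors how the index is used in practice: enumerate every
(normalization, reduction) combination, score each resulting embedding with
the clustering-tendency index, carry the highest-scoring embedding forward
to clustering, and — when reference labels exist — benchmark every
combination with the Adjusted Rand Index to check that the selected path
sits in the upper tail.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .core import Embedding, InvalidInputError, NdrScore, ndrindex_score
from .preprocess import ExpressionMatrix, MethodRegistry

__all__ = [
    "ComboScore",
    "EvaluationReport",
    "enumerate_combos",
    "combo_seed",
    "preprocess_combo",
    "score_all",
    "select_best",
    "cluster_embedding",
    "adjusted_rand_index",
    "evaluate_combos",
]

CLUSTERERS = ("kmeans", "hierarchical")


@dataclass(frozen=True)
class ComboScore:
    """Index score of one preprocessing path, or its failure reason."""

    norm_name: str
    reduction_name: str
    score: NdrScore | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.score is not None


@dataclass(frozen=True)
class EvaluationReport:
    """Tidy per-(combo, clusterer) ARI table plus selection summary."""

    table: pd.DataFrame
    selected: tuple[str, str]
    summary: dict = field(default_factory=dict)


def enumerate_combos(registry: MethodRegistry) -> list[tuple[str, str]]:
    """Full Cartesian product of registered methods, lexicographic order."""
    if not registry.normalizations:
        raise InvalidInputError("registry has no normalizations")
    if not registry.reductions:
        raise InvalidInputError("registry has no reductions")
    return [
        (n, r)
        for n in sorted(registry.normalizations)
        for r in sorted(registry.reductions)
    ]


def combo_seed(seed: int, norm_name: str, reduction_name: str) -> int:
    """Deterministic per-combo sub-seed derived from the top-level seed."""
    digest = hashlib.sha256(
        f"{seed}:{norm_name}:{reduction_name}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def preprocess_combo(
    X: ExpressionMatrix,
    registry: MethodRegistry,
    norm_name: str,
    reduction_name: str,
    seed: int,
) -> Embedding:
    """Apply one normalization then one reduction; the single shared path
    behind both scoring and evaluation."""
    norm = registry.normalizations[norm_name]
    reduce = registry.reductions[reduction_name]
    return reduce(norm(X).counts, combo_seed(seed, norm_name, reduction_name))


def score_all(
    X: ExpressionMatrix,
    registry: MethodRegistry,
    repeats: int = 100,
    seed: int = 0,
) -> list[ComboScore]:
    """Score every combo; preprocessing failures are recorded, not dropped."""
    scores: list[ComboScore] = []
    for norm_name, red_name in enumerate_combos(registry):
        sub = combo_seed(seed, norm_name, red_name)
        try:
            emb = preprocess_combo(X, registry, norm_name, red_name, seed)
            score = ndrindex_score(emb, repeats=repeats, seed=sub)
        except Exception as exc:
            scores.append(ComboScore(norm_name, red_name, None, error=str(exc)))
        else:
            scores.append(ComboScore(norm_name, red_name, score))
    if not any(s.ok for s in scores):
        raise RuntimeError(
            "every preprocessing path failed: "
            + "; ".join(f"{s.norm_name}+{s.reduction_name}: {s.error}" for s in scores)
        )
    return scores


def select_best(scores: list[ComboScore]) -> ComboScore:
    """Argmax of the mean index; exact ties go to the lexicographically
    first (normalization, reduction) name pair."""
    ok = sorted(
        (s for s in scores if s.ok),
        key=lambda s: (s.norm_name, s.reduction_name),
    )
    if not ok:
        raise InvalidInputError("no successfully scored combination to select from")
    # min over the negated mean keeps the first (lexicographically smallest)
    # combo on exact ties
    return min(ok, key=lambda s: -s.score.mean_index)


def cluster_embedding(
    emb: Embedding,
    k: int,
    method: str = "kmeans",
    seed: int = 0,
) -> np.ndarray:
    """Partition an embedding into ``k`` clusters.

    ``kmeans`` is seeded Lloyd's with 10 restarts; ``hierarchical`` is
    Ward-linkage agglomeration cut at ``k`` (deterministic).
    """
    n = emb.n
    if not 2 <= k <= n:
        raise InvalidInputError(f"k={k} outside [2, n={n}]")
    if method == "kmeans":
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        return km.fit_predict(emb.points).astype(np.intp)
    if method == "hierarchical":
        Z = linkage(emb.points, method="ward")
        return (fcluster(Z, t=k, criterion="maxclust") - 1).astype(np.intp)
    raise InvalidInputError(f"unknown clustering method {method!r}")


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected partition agreement in [-1, 1].

    Computed from the contingency table as (Index - Expected) / (Max -
    Expected); identical trivial partitions (the 0/0 form) score 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError(
            f"label vectors must be 1-D and equal length, got {a.shape} vs {b.shape}"
        )
    return float(adjusted_rand_score(a, b))


def evaluate_combos(
    X: ExpressionMatrix,
    registry: MethodRegistry,
    truth: np.ndarray,
    k: int,
    clusterers: tuple[str, ...] = CLUSTERERS,
    repeats: int = 100,
    seed: int = 0,
) -> EvaluationReport:
    """Benchmark every combo x clusterer against reference labels.

    Each combo's embedding is computed once, scored with the tendency index
    and clustered with each requested algorithm; ARIs against ``truth`` fill
    a tidy table.  The summary records, per clusterer, the quantile rank of
    the selected combo's ARI among all successful combos.
    """
    truth = np.asarray(truth)
    if truth.shape[0] != X.n_cells:
        raise InvalidInputError(
            f"truth has {truth.shape[0]} labels for {X.n_cells} cells"
        )
    rows = []
    scores: list[ComboScore] = []
    embeddings: dict[tuple[str, str], Embedding] = {}
    for norm_name, red_name in enumerate_combos(registry):
        sub = combo_seed(seed, norm_name, red_name)
        try:
            emb = preprocess_combo(X, registry, norm_name, red_name, seed)
            score = ndrindex_score(emb, repeats=repeats, seed=sub)
        except Exception as exc:
            scores.append(ComboScore(norm_name, red_name, None, error=str(exc)))
        else:
            scores.append(ComboScore(norm_name, red_name, score))
            embeddings[(norm_name, red_name)] = emb
    best = select_best(scores)
    selected = (best.norm_name, best.reduction_name)

    for s in scores:
        for clusterer in clusterers:
            row = {
                "normalization": s.norm_name,
                "reduction": s.reduction_name,
                "clusterer": clusterer,
                "ndrindex_mean": s.score.mean_index if s.ok else np.nan,
                "ari": np.nan,
                "selected": (s.norm_name, s.reduction_name) == selected,
                "error": s.error,
            }
            if s.ok:
                labels = cluster_embedding(
                    embeddings[(s.norm_name, s.reduction_name)],
                    k=k,
                    method=clusterer,
                    seed=combo_seed(seed, s.norm_name, s.reduction_name + clusterer),
                )
                row["ari"] = adjusted_rand_index(truth, labels)
            rows.append(row)

    table = pd.DataFrame(rows)
    summary: dict = {"selected": selected, "seed": seed, "k": k, "repeats": repeats}
    for clusterer in clusterers:
        sub_tab = table[(table["clusterer"] == clusterer) & table["ari"].notna()]
        aris = sub_tab["ari"].to_numpy()
        sel = sub_tab.loc[sub_tab["selected"], "ari"]
        if len(sel) and len(aris):
            sel_ari = float(sel.iloc[0])
            summary[clusterer] = {
                "selected_ari": sel_ari,
                "median_ari": float(np.median(aris)),
                "upper_quartile_ari": float(np.percentile(aris, 75)),
                "quantile_rank": float(np.mean(aris <= sel_ari)),
            }
    return EvaluationReport(table=table, selected=selected, summary=summary)
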