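"""Independent plain-loop oracles the tests compare the package against.

Everything here is deliberately written in the most literal style possible
(explicit Python loops, no shared code with the package) so that agreement
with the vectorized implementations is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_distances(points: np.ndarray) -> np.ndarray:
    """Double-loop Euclidean distance matrix."""
    n = len(points)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for a, b in zip(points[i], points[j]):
                s += (a - b) ** 2
            out[i, j] = math.sqrt(s)
    return out


def grow_clusters_transcription(points: np.ndarray, scale: float, start: int):
    """Literal transcription of the greedy point-gathering pseudo-code.

    Select a point A (given as ``start``); let it be an individual cluster,
    K = 1.  Repeatedly find, among points not yet in any cluster, the point
    B closest to the geometric center of the active cluster; if that
    distance is smaller than the average scale, add B and update the
    center, otherwise B becomes a new individual cluster (and the active
    one) and K increases.  Stop when every point belongs to a cluster.
    Ties go to the lowest point index.

    Returns (assignments, K, radii, R, index).
    """
    n = len(points)
    clusters = [[start]]
    assigned = {start}

    def center_of(cluster):
        d = len(points[0])
        c = [0.0] * d
        for idx in cluster:
            for a in range(d):
                c[a] += points[idx][a]
        return [v / len(cluster) for v in c]

    def dist(p, q):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))

    while len(assigned) < n:
        center = center_of(clusters[-1])
        best, best_d = None, None
        for idx in range(n):
            if idx in assigned:
                continue
            d = dist(points[idx], center)
            if best is None or d < best_d:
                best, best_d = idx, d
        if best_d < scale:
            clusters[-1].append(best)
        else:
            clusters.append([best])
        assigned.add(best)

    assignments = [0] * n
    radii = []
    for k, cluster in enumerate(clusters):
        c = center_of(cluster)
        total = 0.0
        for idx in cluster:
            assignments[idx] = k
            total += dist(points[idx], c)
        radii.append(total / len(cluster))
    K = len(clusters)
    R = sum(radii) / K
    return assignments, K, radii, R, 1.0 - R / scale


def ari_contingency(a, b) -> float:
    """Adjusted Rand Index straight from the contingency-table formula."""

    def comb2(x):
        return x * (x - 1) / 2.0

    a = list(a)
    b = list(b)
    n = len(a)
    labels_a = sorted(set(a))
    labels_b = sorted(set(b))
    table = {}
    for x, y in zip(a, b):
        table[(x, y)] = table.get((x, y), 0) + 1
    index = sum(comb2(v) for v in table.values())
    sum_a = sum(comb2(a.count(la)) for la in labels_a)
    sum_b = sum(comb2(b.count(lb)) for lb in labels_b)
    expected = sum_a * sum_b / comb2(n)
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:
        return 1.0
    return (index - expected) / (maximum - expected)


def tmm_factor_transcription(counts, ref, i, trim_m=0.30, trim_a=0.05) -> float:
    """Literal trimmed-mean-of-M-values factor of cell ``i`` vs ``ref``
    (before the geometric-mean renormalization)."""
    x = counts[i]
    r = counts[ref]
    Nx = sum(x)
    Nr = sum(r)
    M, A, w = [], [], []
    for g in range(len(x)):
        if x[g] > 0 and r[g] > 0:
            xs = x[g] / Nx
            rs = r[g] / Nr
            M.append(math.log2(xs / rs))
            A.append(0.5 * math.log2(xs * rs))
            w.append(
                1.0
                / ((Nx - x[g]) / (Nx * x[g]) + (Nr - r[g]) / (Nr * r[g]))
            )
    lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
    num = den = 0.0
    any_kept = False
    for m, a, wt in zip(M, A, w):
        if lo_m <= m <= hi_m and lo_a <= a <= hi_a:
            num += m * wt
            den += wt
            any_kept = True
    if not any_kept:
        for m, wt in zip(M, w):
            num += m * wt
            den += wt
    return 2.0 ** (num / den)


def sammon_stress(X, Y) -> float:
    """Double-loop Sammon stress of embedding Y for input X."""
    n = len(X)

    def dist(p, q):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))

    c = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            c += dist(X[i], X[j])
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            D = dist(X[i], X[j])
            d = dist(Y[i], Y[j])
            total += (D - d) ** 2 / D
    return total / c


def sammon_transcription(X, d=2, max_iter=200, tol=1e-9):
    """Plain-loop transcription of the descent used for Sammon mapping:
    PCA initialization, normalized ascent direction on the negative
    gradient, backtracking halving, step doubling after acceptance."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    Y = U[:, :d] * s[:d]

    D = brute_force_distances(X)
    E = sammon_stress(X, Y)
    step = 0.3
    for _ in range(max_iter):
        G = np.zeros_like(Y)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dy = math.sqrt(sum((Y[i] - Y[j]) ** 2))
                dy = max(dy, 1e-12)
                ratio = (D[i, j] - dy) / (D[i, j] * dy)
                G[i] += ratio * (Y[i] - Y[j])
        gnorm = math.sqrt((G**2).sum())
        if gnorm == 0.0:
            break
        direction = G / gnorm
        accepted = False
        trial = step
        for _ in range(30):
            Y_new = Y + trial * direction
            E_new = sammon_stress(X, Y_new)
            if E_new < E:
                accepted = True
                break
            trial /= 2.0
        if not accepted:
            break
        improvement = (E - E_new) / E if E > 0 else 0.0
        Y, E = Y_new, E_new
        step = min(trial * 2.0, 1.0)
        if improvement < tol:
            break
    return Y, E
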