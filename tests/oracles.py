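"""Independent brute-force oracles used to cross-check the implementation.

Each function here recomputes a quantity from its textbook definition with
no shared code paths with the package (plain loops, math.comb, exhaustive
enumeration), so agreement is evidence of correctness rather than identity.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """BH q-values straight from the step-up definition (quadratic loop)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = []
        for later_pos in range(rank_pos, m):
            j = later_pos + 1
            candidates.append(m * p[order[later_pos]] / j)
        q[idx] = min(1.0, min(candidates))
    return q


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct summation."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for [[a, b], [c, d]]."""
    return hypergeom_upper_tail(a + b + c + d, a + c, a + b, a)


def soergel(x: np.ndarray, y: np.ndarray) -> float:
    inter = int(np.sum((x == 1) & (y == 1)))
    union = int(np.sum((x == 1) | (y == 1)))
    return 0.0 if union == 0 else 1.0 - inter / union


def pairwise_auc(probs: np.ndarray, y: np.ndarray) -> float:
    """AUC as the fraction of concordant case/control pairs, ties counted half."""
    pos = probs[y == 1]
    neg = probs[y == 0]
    total = 0.0
    for p1 in pos:
        for p0 in neg:
            if p1 > p0:
                total += 1.0
            elif p1 == p0:
                total += 0.5
    return total / (len(pos) * len(neg))


def silhouette_textbook(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """s(i) from the displayed formula, plain loops, singletons -> 0."""
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            continue
        a = sum(d[i, j] for j in same) / len(same)
        b = math.inf
        for other in set(labels.tolist()) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            b = min(b, sum(d[i, j] for j in members) / len(members))
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


def average_linkage_naive(d: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) agglomeration recomputing average distances from the raw matrix.

    Returns (members_i, members_j, height) per merge with the same
    lowest-(i, j) tie rule as the implementation (clusters indexed by
    creation order).
    """
    n = d.shape[0]
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i:
                    continue
                avg = float(
                    np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                )
                key = (avg, i, j)
                if best is None or key < best:
                    best = key
        avg, i, j = best
        merges.append((clusters[i], clusters[j], avg))
        clusters[next_id] = clusters[i] | clusters[j]
        del clusters[i], clusters[j]
        next_id += 1
    return merges
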