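"""Brute-force reference implementations used only as test oracles.

Each oracle recomputes a statistic from first principles (enumeration of
draws, enumeration of label permutations, naive agglomeration) independently
of the library code paths it checks.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np


def hypergeom_upper_tail_by_enumeration(N: int, M: int, n: int) -> dict[int, float]:
    """P(X >= x) for every x, by enumerating all C(N, n) draws.

    The universe is 0..N-1 with the first M elements category members.
    Returns {x: P(X >= x)} for x in 0..min(M, n).
    """
    counts: Counter[int] = Counter()
    total = 0
    for draw in itertools.combinations(range(N), n):
        counts[sum(1 for g in draw if g < M)] += 1
        total += 1
    upper = {}
    running = 0
    for x in range(min(M, n), -1, -1):
        running += counts.get(x, 0)
        upper[x] = running / total
    return upper


def _ranks_with_ties(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def kruskal_h_by_hand(groups: list[list[float]]) -> float:
    """H = 12/(N(N+1)) sum R_i^2/n_i - 3(N+1), with the standard tie correction."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = _ranks_with_ties(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    ties = Counter(pooled)
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


def kruskal_exact_p_by_permutation(groups: list[list[float]]) -> tuple[float, float]:
    """(H, exact P) by enumerating every assignment of values to groups."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    h_obs = kruskal_h_by_hand(groups)
    count = 0
    total = 0
    for perm in itertools.permutations(pooled):
        regrouped = []
        start = 0
        for sz in sizes:
            regrouped.append(list(perm[start : start + sz]))
            start += sz
        if kruskal_h_by_hand(regrouped) >= h_obs - 1e-9:
            count += 1
        total += 1
    return h_obs, count / total


def upgma_cophenetic_by_hand(dist: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix from naive average-linkage agglomeration.

    Clusters merge at the unweighted mean of all between-cluster leaf
    distances; the merge height becomes the cophenetic distance of every
    cross pair.
    """
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros_like(dist)

    def avg_dist(a: list[int], b: list[int]) -> float:
        return float(np.mean([dist[i, j] for i in a for j in b]))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = avg_dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = d
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return coph
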