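"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (enumeration, direct formulas,
O(n^3) loops) and shares no code with the implementation under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def mannwhitney_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every label split.

    Tie-free data only.  p = min(1, 2 * min(P(U1 <= u), P(U1 >= u))) over
    the permutation distribution of U1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = x.size
    n = pooled.size

    def u1_of(group_x: np.ndarray, group_y: np.ndarray) -> float:
        return float(sum((xi > yj) for xi in group_x for yj in group_y))

    u_obs = u1_of(x, y)
    us = []
    idx = np.arange(n)
    for chosen in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(chosen)] = True
        us.append(u1_of(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def students_t_formula(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t statistic and df by the textbook formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), float(n1 + n2 - 2)


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjustment from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def naive_ward(points: np.ndarray):
    """O(n^3) Ward agglomeration from cluster centroids.

    Returns the merge sequence as a list of (frozenset_a, frozenset_b,
    height) with height = sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A -
    centroid_B|| (the scale used by standard linkage outputs).
    """
    points = np.asarray(points, float)
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(points.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                ca = points[list(a)].mean(axis=0)
                cb = points[list(b)].mean(axis=0)
                na, nb = len(a), len(b)
                cost = 2.0 * na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        a, b = clusters[i], clusters[j]
        merges.append((a, b, float(np.sqrt(cost))))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(a | b)
    return merges


def linkage_to_merges(Z: np.ndarray, n: int):
    """Convert a linkage matrix to the naive_ward merge representation."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_i, (a, b, h, _) in enumerate(Z):
        fa, fb = members[int(a)], members[int(b)]
        merges.append((fa, fb, float(h)))
        members[n + row_i] = fa | fb
    return merges


def auc_concordance(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by direct enumeration of concordant / tied pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    pos = scores[labels == classes[1]]
    neg = scores[labels == classes[0]]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (pos.size * neg.size)


def rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Rand index between two labelings."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            agree += same_a == same_b
    return agree / (n * (n - 1) / 2)
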