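"""Independent brute-force reference implementations used as test oracles.

Deliberately naive (explicit loops, first-principles formulas) and kept
separate from the package code paths they check.
"""

import numpy as np


def brute_levins(props):
    p = [x / sum(props) for x in props]
    return 1.0 / sum(x * x for x in p), sum(1 for x in p if x > 0)


def brute_pianka(p, q):
    num = sum(a * b for a, b in zip(p, q))
    den = (sum(a * a for a in p) * sum(b * b for b in q)) ** 0.5
    return num / den


def brute_bray_curtis(x, y):
    return 1.0 - 2.0 * sum(min(a, b) for a, b in zip(x, y)) / (sum(x) + sum(y))


def brute_kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H from first principles (mid-ranks)."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty_like(pooled)
    sorted_vals = pooled[order]
    i, pos = 0, 1
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        midrank = (pos + (pos + j - i - 1)) / 2.0
        for k in range(i, j):
            ranks[order[k]] = midrank
        pos += j - i
        i = j
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1 - ((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    return h / correction


def naive_upgma_cophenetic(ids, D):
    """Agglomerate by smallest average inter-cluster distance; return the
    cophenetic distance (merge height) for every leaf pair."""
    D = np.asarray(D, dtype=float)
    index = {name: i for i, name in enumerate(ids)}
    clusters = [frozenset([name]) for name in ids]
    coph = {}
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = np.mean(
                    [
                        D[index[x], index[y]]
                        for x in clusters[a]
                        for y in clusters[b]
                    ]
                )
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        for x in clusters[a]:
            for y in clusters[b]:
                coph[frozenset([x, y])] = dist
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return coph
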