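"""Independent brute-force oracles used by the test suite.

Deliberately naive: exhaustive enumeration, direct pair counting, no shared
code with the implementations they check.
"""

from itertools import combinations

import numpy as np


def dtw_brute(x, y):
    """Minimal warping-path cost by explicit enumeration of every monotone
    boundary-to-boundary path (feasible for n <= ~6)."""
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + abs(x[i] - y[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def rand_brute(pred, truth):
    """Rand index by explicitly scoring every pair of objects."""
    pred = list(pred)
    truth = list(truth)
    agree = total = 0
    for a, b in combinations(range(len(pred)), 2):
        total += 1
        same_p = pred[a] == pred[b]
        same_t = truth[a] == truth[b]
        agree += same_p == same_t
    return 1.0 if total == 0 else agree / total


def kmedoids_exhaustive(dist, k):
    """Globally optimal k-medoids by enumerating every medoid subset."""
    n = dist.shape[0]
    best_cost, best_medoids = np.inf, None
    for medoids in combinations(range(n), k):
        cost = dist[list(medoids)].min(axis=0).sum()
        if cost < best_cost:
            best_cost, best_medoids = cost, medoids
    return best_cost, best_medoids
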