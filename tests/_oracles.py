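"""Independent oracle implementations used only by the test suite.

These deliberately avoid the library code paths they check: closed-form
statistics written from the textbook formulas, and an exact
dynamic-programming optimal 1-D k-partition.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_r_closed_form(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float(np.sum(dx * dy) / math.sqrt(np.sum(dx**2) * np.sum(dy**2)))


def paired_t_closed_form(x, y) -> float:
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    sd = math.sqrt(np.sum((d - d.mean()) ** 2) / (n - 1))
    return float(d.mean() / (sd / math.sqrt(n)))


def anova_f_closed_form(groups) -> float:
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    return float((ss_between / (k - 1)) / (ss_within / (n_total - k)))


def optimal_1d_kmeans(values, k: int) -> np.ndarray:
    """Exact optimal 1-D k-partition by dynamic programming, O(k n^2).

    Returns 1-based cluster assignments in input order, cluster 1 having
    the largest mean (matching the library's labelling convention).
    """
    x = np.asarray(values, float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    prefix = np.concatenate([[0.0], np.cumsum(xs)])
    prefix2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def sse(i, j):  # within-cluster sum of squares of xs[i:j]
        s = prefix[j] - prefix[i]
        s2 = prefix2[j] - prefix2[i]
        m = j - i
        return s2 - s * s / m

    inf = float("inf")
    cost = np.full((k + 1, n + 1), inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, best_i = inf, m - 1
            for i in range(m - 1, j):
                c = cost[m - 1, i] + sse(i, j)
                if c < best:
                    best, best_i = c, i
            cost[m, j] = best
            split[m, j] = best_i
    # backtrack cluster boundaries over sorted data
    labels_sorted = np.zeros(n, dtype=int)
    j = n
    for m in range(k, 0, -1):
        i = split[m, j]
        labels_sorted[i:j] = m  # ascending value order -> label m
        j = i
    # ascending clusters k..1 -> cluster 1 = largest mean
    assignments = np.empty(n, dtype=int)
    assignments[order] = (k + 1) - labels_sorted
    return assignments
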