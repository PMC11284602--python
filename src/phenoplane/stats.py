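"""Validation and field-analysis statistics.

Covers the pipeline's evaluation toolkit: paired validation of measured
vs. predicted trait values (Pearson r, R^2, RMSE, paired t, detection
frequency), deterministic 1-D k-means size clustering, and one-way ANOVA
with Tukey HSD pairwise comparisons compressed to a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateGroups,
    InsufficientPairs,
    TooFewSamples,
)

__all__ = [
    "ClusterResult",
    "ValidationReport",
    "anova_tukey",
    "cluster_response_analysis",
    "kmeans_clusters",
    "validate_trait",
]


@dataclass(frozen=True)
class ValidationReport:
    trait: str
    n: int
    pearson_r: float
    r_squared: float
    rmse: float
    t_stat: float
    p_paired: float
    detection_frequency_pct: float


def validate_trait(measured, predicted, attempts: int, trait: str = "") -> ValidationReport:
    """Agreement statistics between conventional and pipeline measurements.

    ``attempts`` is the number of measurement attempts; successful pairs
    number ``n = len(measured)``, giving detection frequency 100*n/attempts.
    Raises :class:`InsufficientPairs` for n < 3.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise ValueError("measured and predicted must be equal-length 1-D")
    if not (np.isfinite(m).all() and np.isfinite(p).all()):
        raise ValueError("inputs must be finite")
    n = len(m)
    if n < 3:
        raise InsufficientPairs(f"need >= 3 pairs, got {n}")
    if attempts < n:
        raise ValueError("attempts must be >= number of successful pairs")

    r, _ = sps.pearsonr(m, p)
    rmse = float(np.sqrt(np.mean((m - p) ** 2)))
    diff = m - p
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            t_stat, p_paired = 0.0, 1.0
        else:  # constant nonzero offset: infinitely significant
            t_stat, p_paired = float(np.sign(diff[0]) * np.inf), 0.0
    else:
        t_stat, p_paired = sps.ttest_rel(m, p)
    return ValidationReport(
        trait=trait,
        n=n,
        pearson_r=float(r),
        r_squared=float(r) ** 2,
        rmse=rmse,
        t_stat=float(t_stat),
        p_paired=float(p_paired),
        detection_frequency_pct=100.0 * n / attempts,
    )


# ---------------------------------------------------------------------------
# 1-D k-means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterResult:
    """Size-cluster assignment, cluster 1 = largest mean.

    ``assignments`` are 1-based cluster indices aligned with the input
    order.  The ANOVA/Tukey fields are populated by
    :func:`cluster_response_analysis` and are ``None`` after plain
    clustering.
    """

    k: int
    assignments: np.ndarray
    cluster_means: np.ndarray  # sorted descending
    anova_f: float | None = None
    anova_p: float | None = None
    tukey_letters: tuple[str, ...] | None = None


def _kmeans_pp_init(xs: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [xs[rng.integers(len(xs))]]
    for _ in range(1, k):
        d2 = np.min((xs[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total == 0:
            centers.append(xs[rng.integers(len(xs))])
        else:
            centers.append(xs[rng.choice(len(xs), p=d2 / total)])
    return np.sort(np.asarray(centers, dtype=float))


def kmeans_clusters(values, k: int = 3, seed: int = 0) -> ClusterResult:
    """Converged 1-D k-means with seeded k-means++ initialization.

    The input is sorted internally before initialization and Lloyd
    iteration, so assignments are invariant to input permutation and fully
    deterministic for a given seed.  Clusters are relabelled by descending
    mean (cluster 1 = largest values).  Raises :class:`TooFewSamples` when
    n < k.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < k:
        raise TooFewSamples(f"need >= {k} samples, got {len(x)}")
    if k < 2:
        raise ValueError("k must be >= 2")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    rng = np.random.default_rng(seed)
    centers = _kmeans_pp_init(xs, k, rng)
    assign_sorted = np.zeros(len(xs), dtype=int)
    for _ in range(300):
        boundaries = (centers[:-1] + centers[1:]) / 2
        new_assign = np.searchsorted(boundaries, xs)
        new_centers = centers.copy()
        for j in range(k):
            sel = new_assign == j
            if sel.any():
                new_centers[j] = xs[sel].mean()
            else:  # re-seed an empty cluster at the worst-fit point
                d2 = (xs - centers[new_assign]) ** 2
                new_centers[j] = xs[np.argmax(d2)]
                new_centers = np.sort(new_centers)
        if np.array_equal(new_assign, assign_sorted) and np.allclose(
            new_centers, centers
        ):
            break
        assign_sorted, centers = new_assign, np.sort(new_centers)

    means = np.array([xs[assign_sorted == j].mean() for j in range(k)])
    rank = np.argsort(-means)  # rank[i] = old label of i-th largest cluster
    relabel = np.empty(k, dtype=int)
    relabel[rank] = np.arange(1, k + 1)
    assignments = np.empty(len(x), dtype=int)
    assignments[order] = relabel[assign_sorted]
    return ClusterResult(k=k, assignments=assignments,
                         cluster_means=means[rank])


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD with compact letter display
# ---------------------------------------------------------------------------

def _compact_letters(means: np.ndarray, not_different: np.ndarray) -> list[str]:
    """Compact letter display from the pairwise 'not different' adjacency.

    Each maximal clique of mutually non-different groups receives one
    letter; groups sharing a letter are therefore never significantly
    different, and significantly different groups never share one.  Letters
    are ordered by the largest group mean they cover.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(means)))
    for i in range(len(means)):
        for j in range(i + 1, len(means)):
            if not_different[i, j]:
                g.add_edge(i, j)
    cliques = sorted(nx.find_cliques(g), key=lambda c: -max(means[list(c)]))
    letters = [""] * len(means)
    for letter_idx, clique in enumerate(cliques):
        ch = chr(ord("a") + letter_idx)
        for node in clique:
            letters[node] += ch
    return ["".join(sorted(s)) for s in letters]


def anova_tukey(groups, alpha: float = 0.05):
    """One-way ANOVA F and p plus Tukey HSD compact letters.

    ``groups`` is a sequence of >= 2 samples, each with n >= 2.  Raises
    :class:`DegenerateGroups` when the pooled data has zero variance.
    Returns ``(F, p, letters)`` with one letter string per group, in input
    order.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise DegenerateGroups("all observations are identical")
    f_stat, p_value = sps.f_oneway(*arrays)
    means = np.array([a.mean() for a in arrays])
    if all(np.ptp(a) == 0 for a in arrays):
        # zero within-group variance: every unequal pair differs exactly
        nd = np.isclose(means[:, None], means[None, :])
    else:
        tukey = sps.tukey_hsd(*arrays)
        nd = tukey.pvalue >= alpha
    letters = _compact_letters(means, nd)
    return float(f_stat), float(p_value), letters


def cluster_response_analysis(
    sizes, responses, k: int = 3, seed: int = 0, alpha: float = 0.05
) -> ClusterResult:
    """Cluster samples by a size trait, then compare a response across clusters.

    K-means (k defaults to 3: large/medium/small) assigns clusters on
    ``sizes``; one-way ANOVA + Tukey letters are computed on ``responses``
    grouped by cluster.  Letters are indexed by cluster (position 0 =
    cluster 1, the largest sizes).
    """
    sizes = np.asarray(sizes, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if sizes.shape != responses.shape:
        raise ValueError("sizes and responses must align")
    base = kmeans_clusters(sizes, k=k, seed=seed)
    groups = [responses[base.assignments == c] for c in range(1, k + 1)]
    if any(len(g) < 2 for g in groups):
        raise DegenerateGroups("a cluster has fewer than 2 samples")
    f_stat, p_value, letters = anova_tukey(groups, alpha=alpha)
    return ClusterResult(
        k=k,
        assignments=base.assignments,
        cluster_means=base.cluster_means,
        anova_f=f_stat,
        anova_p=p_value,
        tukey_letters=tuple(letters),
    )
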