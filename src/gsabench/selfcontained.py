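"""Self-contained multivariate gene-set tests.

Three test statistics compare the two phenotype groups of a gene set's
expression submatrix, treating samples as points in R^p:

* ``n_stat`` — the N-statistic (energy-type test of F_x = F_y) built from
  mean between- and within-group Euclidean distances.
* ``sam_gs_stat`` — SAM-GS, the squared L2 norm of per-gene moderated
  t-like statistics (mean difference over pooled SD plus a small s0).
* ``mst_ks_stat`` — a multivariate Kolmogorov-Smirnov statistic that ranks
  the pooled samples by a traversal of their Euclidean minimum spanning
  tree and takes the maximal ECDF difference along that ranking.

Significance always comes from subject sampling: the statistic is
recomputed under permuted sample labels (exhaustively enumerated when the
number of distinct splits is small).  By convention the N-statistic and the
MST-KS test run on RPKM values and SAM-GS on log-CPM.
"""

from __future__ import annotations

from collections import deque
from typing import Callable

import numpy as np
import pandas as pd

from gsabench._batch import group_moments, iter_mask_chunks, set_row_blocks
from gsabench._perm import GeneSetTestResult, TestConfig, pvalues_from_null, split_masks
from gsabench.normalize import log_cpm, rpkm
from gsabench.simulate import CountDataset, GeneSetCollection

__all__ = [
    "TestConfig",
    "GeneSetTestResult",
    "sam_gs_stat",
    "n_stat",
    "mst_ks_stat",
    "mst_ranking",
    "permutation_pvalue",
    "nstat_test_collection",
    "samgs_test_collection",
    "mstks_test_collection",
]


# ---------------------------------------------------------------------------
# statistics


def sam_gs_stat(X: np.ndarray, Y: np.ndarray, s0: float = 0.0) -> float:
    """SAM-GS statistic: sum over genes of squared
    ``(mean(X_i) - mean(Y_i)) / (pooled_sd_i + s0)``.

    ``X`` and ``Y`` are genes x samples submatrices for the two phenotypes
    (same gene rows).  The pooled SD uses the two-group pooled variance with
    ``n1 + n2 - 2`` denominator.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same gene rows")
    n1, n2 = X.shape[1], Y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    d = X.mean(axis=1) - Y.mean(axis=1)
    ss = X.var(axis=1, ddof=1) * (n1 - 1) + Y.var(axis=1, ddof=1) * (n2 - 1)
    sd = np.sqrt(ss / (n1 + n2 - 2))
    if s0 == 0.0 and np.any(sd == 0.0):
        raise ValueError(
            "zero pooled SD with s0 = 0; use a positive s0 (see TestConfig.s0_policy)"
        )
    t = d / (sd + s0)
    return float(np.sum(t * t))


def _pairwise_distances(points: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between the columns of ``points`` (p x n)."""
    G = points.T @ points
    sq = np.diag(G)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * G, 0.0)
    return np.sqrt(D2)


def n_stat(X: np.ndarray, Y: np.ndarray) -> float:
    """N-statistic between two multivariate samples (columns are samples).

    ``(n1 n2 / (n1 + n2)) * sqrt(B - W1 - W2)`` where B is the mean
    between-group Euclidean distance and W1, W2 are half the mean
    within-group distances; the bracket is clipped at zero before the root
    to absorb round-off.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must live in the same R^p")
    n1, n2 = X.shape[1], Y.shape[1]
    if n1 < 1 or n2 < 1:
        raise ValueError("each group needs at least 1 sample")
    pooled = np.hstack([X, Y])
    D = _pairwise_distances(pooled)
    between = D[:n1, n1:].sum() / (n1 * n2)
    within1 = D[:n1, :n1].sum() / (2.0 * n1 * n1)
    within2 = D[n1:, n1:].sum() / (2.0 * n2 * n2)
    bracket = max(between - within1 - within2, 0.0)
    return float(n1 * n2 / (n1 + n2) * np.sqrt(bracket))


# ---------------------------------------------------------------------------
# minimum spanning tree ranking


def _prim_mst(D: np.ndarray) -> list[tuple[int, int, float]]:
    """Prim's algorithm on a dense distance matrix; returns tree edges
    ``(u, v, weight)``.  Ties are broken by lowest sample index (argmin),
    so duplicate points are handled deterministically."""
    n = D.shape[0]
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = D[0].astype(float).copy()
    best[0] = np.inf
    best_from = np.zeros(n, dtype=np.intp)
    edges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        masked = np.where(in_tree, np.inf, best)
        v = int(np.argmin(masked))
        u = int(best_from[v])
        edges.append((u, v, float(D[u, v])))
        in_tree[v] = True
        closer = D[v] < best
        best = np.where(closer, D[v], best)
        best_from = np.where(closer, v, best_from)
        best[v] = np.inf
    return edges


def mst_total_weight(D: np.ndarray) -> float:
    """Total weight of the Euclidean MST (used by equivalence checks)."""
    return float(sum(w for _, _, w in _prim_mst(D)))


def mst_ranking(D: np.ndarray) -> np.ndarray:
    """Rank samples by a rooted depth-first traversal of their MST.

    The root is a node of maximum (hop-count) eccentricity in the tree,
    ties broken by lowest index; children are visited in increasing
    edge-weight order, ties again by lowest index.  Returns the visiting
    order of sample indices.
    """
    n = D.shape[0]
    if n == 1:
        return np.zeros(1, dtype=np.intp)
    edges = _prim_mst(D)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for u, v, w in edges:
        adj[u].append((v, w))
        adj[v].append((u, w))

    def eccentricity(start: int) -> int:
        dist = np.full(n, -1)
        dist[start] = 0
        q = deque([start])
        while q:
            x = q.popleft()
            for y, _ in adj[x]:
                if dist[y] < 0:
                    dist[y] = dist[x] + 1
                    q.append(y)
        return int(dist.max())

    ecc = [eccentricity(i) for i in range(n)]
    root = int(np.argmax(ecc))  # argmax takes the lowest index on ties

    order: list[int] = []
    visited = np.zeros(n, dtype=bool)
    stack = [root]
    while stack:
        x = stack.pop()
        if visited[x]:
            continue
        visited[x] = True
        order.append(x)
        children = sorted(
            ((w, y) for y, w in adj[x] if not visited[y]), key=lambda t: (t[0], t[1])
        )
        # push in reverse so the smallest-weight child is visited first
        for w, y in reversed(children):
            stack.append(y)
    return np.array(order, dtype=np.intp)


def _ks_along_order(masks: np.ndarray, order: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Max ECDF difference along a fixed sample order, per mask row."""
    Mo = masks[:, order]
    c1 = np.cumsum(Mo, axis=1) / n1
    c2 = np.cumsum(~Mo, axis=1) / n2
    return np.abs(c1 - c2).max(axis=1)


def mst_ks_stat(X: np.ndarray, Y: np.ndarray) -> float:
    """Multivariate KS statistic based on the MST ranking of the pooled
    samples: ``max_r |#{group 1 among first r}/n1 - #{group 2}/n2|``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must live in the same R^p")
    n1, n2 = X.shape[1], Y.shape[1]
    if n1 + n2 < 3:
        raise ValueError("need at least 3 pooled samples")
    pooled = np.hstack([X, Y])
    D = _pairwise_distances(pooled)
    order = mst_ranking(D)
    mask = np.zeros((1, n1 + n2), dtype=bool)
    mask[0, :n1] = True
    return float(_ks_along_order(mask, order, n1, n2)[0])


# ---------------------------------------------------------------------------
# permutation engine


def permutation_pvalue(
    stat_fn: Callable[[np.ndarray, np.ndarray], float],
    values: np.ndarray,
    labels: np.ndarray,
    config: TestConfig,
    method: str = "custom",
    set_name: str = "set",
) -> GeneSetTestResult:
    """Subject-sampling P-value for an arbitrary set-level statistic.

    ``values`` is the genes x samples submatrix of one gene set, already on
    the scale the statistic expects; ``labels`` holds the phenotype tags.
    Large statistics count as evidence against H0.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    if values.shape[1] != labels.size:
        raise ValueError("values columns must match labels")
    masks, exhaustive = split_masks(labels, config)
    stats = np.array(
        [stat_fn(values[:, m], values[:, ~m]) for m in masks], dtype=float
    )
    p = float(pvalues_from_null(stats[None, :], exhaustive)[0])
    return GeneSetTestResult(
        set_name=set_name,
        statistic=float(stats[0]),
        p_value=p,
        method=method,
        n_perm_used=masks.shape[0] - 1,
    )


def _results_frame(names, stats, pvals, method, n_perm) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": names,
            "method": method,
            "statistic": stats,
            "p_value": pvals,
            "n_perm": n_perm,
        }
    )


def _set_indices(dataset: CountDataset, sets: GeneSetCollection) -> list[np.ndarray]:
    return [dataset.gene_indices(sets.sets[name]) for name in sets.names()]


# ---------------------------------------------------------------------------
# vectorised whole-collection runners


def nstat_test_collection(
    dataset: CountDataset, sets: GeneSetCollection, config: TestConfig
) -> pd.DataFrame:
    """N-statistic permutation test for every set (RPKM values)."""
    expr = rpkm(dataset).values
    masks, exhaustive = split_masks(dataset.labels, config)
    M = masks.astype(float)
    n1 = int(masks[0].sum())
    n2 = masks.shape[1] - n1
    names = sets.names()
    stats = np.empty((len(names), masks.shape[0]))
    for k, idx in enumerate(_set_indices(dataset, sets)):
        D = _pairwise_distances(expr[idx])
        R = M @ D  # R[b, i] = sum_{j in group1(b)} D[i, j]
        W1 = (R * M).sum(axis=1)
        cross = R.sum(axis=1) - W1
        W2 = D.sum() - W1 - 2.0 * cross
        bracket = cross / (n1 * n2) - W1 / (2.0 * n1 * n1) - W2 / (2.0 * n2 * n2)
        stats[k] = n1 * n2 / (n1 + n2) * np.sqrt(np.maximum(bracket, 0.0))
    pvals = pvalues_from_null(stats, exhaustive)
    return _results_frame(names, stats[:, 0], pvals, "nstat", masks.shape[0] - 1)


def mstks_test_collection(
    dataset: CountDataset, sets: GeneSetCollection, config: TestConfig
) -> pd.DataFrame:
    """MST-ranking KS permutation test for every set (RPKM values).

    The MST and its traversal depend on the data only, so they are built
    once per set and the label splits just re-walk the fixed ranking.
    """
    expr = rpkm(dataset).values
    masks, exhaustive = split_masks(dataset.labels, config)
    n1 = int(masks[0].sum())
    n2 = masks.shape[1] - n1
    names = sets.names()
    stats = np.empty((len(names), masks.shape[0]))
    for k, idx in enumerate(_set_indices(dataset, sets)):
        D = _pairwise_distances(expr[idx])
        order = mst_ranking(D)
        stats[k] = _ks_along_order(masks, order, n1, n2)
    pvals = pvalues_from_null(stats, exhaustive)
    return _results_frame(names, stats[:, 0], pvals, "mstks", masks.shape[0] - 1)


def samgs_test_collection(
    dataset: CountDataset, sets: GeneSetCollection, config: TestConfig
) -> pd.DataFrame:
    """SAM-GS permutation test for every set (log-CPM values).

    ``s0`` is resolved once from the observed labeling (per
    ``config.s0_policy``) and held fixed across permutations.
    """
    E = log_cpm(dataset).values
    masks, exhaustive = split_masks(dataset.labels, config)
    m1, v1, m2, v2, n1, n2 = group_moments(E, masks[:1])
    sd_obs = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2)[:, 0] / (n1 + n2 - 2))
    s0 = config.s0_value(sd_obs)

    index_lists = _set_indices(dataset, sets)
    rows, starts = set_row_blocks(index_lists)
    if s0 == 0.0 and np.any(sd_obs[rows] == 0.0):
        raise ValueError(
            "zero pooled SD with s0 = 0; use a positive s0 (see TestConfig.s0_policy)"
        )
    names = sets.names()
    stats = np.empty((len(names), masks.shape[0]))
    for off, block in iter_mask_chunks(masks):
        m1, v1, m2, v2, n1, n2 = group_moments(E, block)
        sd = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
        t = (m1 - m2) / (sd + s0)
        tsq = t * t
        stats[:, off : off + block.shape[0]] = np.add.reduceat(tsq[rows], starts, axis=0)
    pvals = pvalues_from_null(stats, exhaustive)
    return _results_frame(names, stats[:, 0], pvals, "samgs", masks.shape[0] - 1)
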