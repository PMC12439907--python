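"""Hungarian-algorithm stitching of window clusters into region-long series.

Consecutive windows are matched pairwise: the cost of pairing cluster i of
window N with cluster j of window N+1 is the masked Hamming distance of
their mean profiles restricted to the bins the two windows share. Solving
the resulting assignment problem per window pair and chaining the
permutations left to right yields t cluster series spanning the region.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .types import BinnedReadMatrix, ClusterSeries, WindowClustering
from .window_cluster import masked_distance

logger = logging.getLogger(__name__)

#: cost attached to empty (padded) clusters so real clusters pair first
EMPTY_CLUSTER_COST = 1.0


def build_cost(
    clus_a: WindowClustering,
    clus_b: WindowClustering,
    disjoint_distance: float = 0.0,
) -> np.ndarray:
    """Cost matrix D[i, j] = d_H(mu_i^N, mu_j^{N+1}) over the shared overlap bins.

    Clusters with no members enter at cost ``EMPTY_CLUSTER_COST`` against
    everything. Rows or columns whose mean profile is entirely missing on
    the overlap fall back to the formula's 0 (with a warning).
    """
    if clus_a.t != clus_b.t:
        raise ValueError("windows carry different cluster counts")
    shared, ia, ib = np.intersect1d(
        clus_a.window.valid_bin_indices,
        clus_b.window.valid_bin_indices,
        return_indices=True,
    )
    if len(shared) == 0:
        raise ValueError(
            f"windows {clus_a.window.index} and {clus_b.window.index} share no bins"
        )
    mu_a = clus_a.mu[:, ia]
    mu_b = clus_b.mu[:, ib]
    t = clus_a.t
    D = np.empty((t, t))
    empty_a = clus_a.cluster_sizes() == 0
    empty_b = clus_b.cluster_sizes() == 0
    warned = False
    for i in range(t):
        for j in range(t):
            if empty_a[i] or empty_b[j]:
                D[i, j] = EMPTY_CLUSTER_COST
                continue
            m = ~np.isnan(mu_a[i]) & ~np.isnan(mu_b[j])
            if not m.any() and not warned:
                warnings.warn(
                    f"cluster pair ({i},{j}) of windows "
                    f"{clus_a.window.index}/{clus_b.window.index} shares no "
                    "observed overlap bins; formula gives distance "
                    f"{disjoint_distance}",
                    stacklevel=2,
                )
                warned = True
            D[i, j] = masked_distance(mu_a[i], mu_b[j], disjoint_distance)
    return D


def _lap_min_cost(cost: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the assignment problem by shortest augmenting paths (O(n^3))."""
    a = np.asarray(cost, dtype=float)
    n = a.shape[0]
    INF = float("inf")
    u = np.zeros(n + 1)
    v = np.zeros(n + 1)
    p = np.zeros(n + 1, dtype=int)  # p[j] = row assigned to column j (1-based)
    way = np.zeros(n + 1, dtype=int)
    for i in range(1, n + 1):
        p[0] = i
        j0 = 0
        minv = np.full(n + 1, INF)
        used = np.zeros(n + 1, dtype=bool)
        while True:
            used[j0] = True
            i0 = p[j0]
            delta = INF
            j1 = -1
            for j in range(1, n + 1):
                if used[j]:
                    continue
                cur = a[i0 - 1, j - 1] - u[i0] - v[j]
                if cur < minv[j]:
                    minv[j] = cur
                    way[j] = j0
                if minv[j] < delta:
                    delta = minv[j]
                    j1 = j
            for j in range(n + 1):
                if used[j]:
                    u[p[j]] += delta
                    v[j] -= delta
                else:
                    minv[j] -= delta
            j0 = j1
            if p[j0] == 0:
                break
        while True:
            j1 = way[j0]
            p[j0] = p[j1]
            j0 = j1
            if j0 == 0:
                break
    perm = np.empty(n, dtype=int)
    for j in range(1, n + 1):
        perm[p[j] - 1] = j - 1
    total = float(a[np.arange(n), perm].sum())
    return perm, total


def hungarian(D: np.ndarray) -> np.ndarray:
    """Minimum-cost perfect matching of a square cost matrix.

    Returns the permutation sigma with sigma[i] = matched column of row i,
    minimizing sum_i D[i, sigma(i)]. Among equally optimal assignments the
    lexicographically smallest permutation is returned, so the result is
    deterministic (a zero matrix maps to the identity).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"cost matrix must be square, got shape {D.shape}")
    n = D.shape[0]
    if n == 0:
        return np.empty(0, dtype=int)
    _, best = _lap_min_cost(D)

    # fix rows greedily to the smallest column keeping the optimum attainable
    # large enough that any matching using a forbidden entry beats no optimum
    FORBIDDEN = 2.0 * n * (np.abs(D).max() + 1.0) if np.isfinite(D).all() else 1e30
    work = D.copy()
    perm = np.empty(n, dtype=int)
    tol = 1e-9 * max(1.0, abs(best))
    for i in range(n):
        row_backup = work[i].copy()
        for j in np.argsort(row_backup, kind="stable"):
            work[i, :] = FORBIDDEN
            work[i, j] = row_backup[j]
            _, total = _lap_min_cost(work)
            if total <= best + tol:
                perm[i] = j
                work[:, j] = FORBIDDEN
                work[i, j] = row_backup[j]
                break
        else:  # pragma: no cover - optimum always attainable
            raise RuntimeError("failed to realize the optimal assignment")
    return perm


def stitch_all(
    clusterings: list[WindowClustering],
    n_bins: int,
    disjoint_distance: float = 0.0,
    collect_diagnostics: bool = False,
) -> tuple[list[ClusterSeries], list[dict]]:
    """Chain pairwise Hungarian matchings into t region-spanning series.

    Series k starts from cluster k of window 0; its region-level profile is
    assembled from the chained per-window mean profiles, averaging the
    (observed) values of overlapping bins with equal weight per window.
    """
    if not clusterings:
        raise ValueError("no window clusterings to stitch")
    t = clusterings[0].t
    chains = np.tile(np.arange(t), (len(clusterings), 1))  # chains[N, k]
    diagnostics: list[dict] = []
    for N in range(len(clusterings) - 1):
        D = build_cost(clusterings[N], clusterings[N + 1], disjoint_distance)
        perm = hungarian(D)
        chains[N + 1] = perm[chains[N]]
        if collect_diagnostics:
            diagnostics.append(
                {
                    "window_pair": [N, N + 1],
                    "cost_matrix": D.tolist(),
                    "permutation": perm.tolist(),
                }
            )

    series: list[ClusterSeries] = []
    for k in range(t):
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        for N, clus in enumerate(clusterings):
            mu = clus.mu[chains[N, k]]
            obs = ~np.isnan(mu)
            idx = clus.window.valid_bin_indices[obs]
            sums[idx] += mu[obs]
            counts[idx] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            profile = sums / counts
        profile[counts == 0] = np.nan
        series.append(
            ClusterSeries(
                series_id=k,
                window_cluster_ids=[int(c) for c in chains[:, k]],
                profile=profile,
            )
        )
    return series, diagnostics


def series_profiles(series: list[ClusterSeries]) -> np.ndarray:
    """Stack series region profiles into a (t, n_bins) matrix."""
    return np.vstack([s.profile for s in series])


def recompute_profiles(
    matrix: BinnedReadMatrix, labels: np.ndarray, t: int
) -> np.ndarray:
    """Mean profile per series from a global label vector (-1 = unassigned)."""
    profiles = np.full((t, matrix.grid.n_bins), np.nan)
    for k in range(t):
        rows = matrix.values[labels == k]
        if rows.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            profiles[k] = np.nanmean(rows, axis=0)
    return profiles
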