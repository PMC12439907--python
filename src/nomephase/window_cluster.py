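"""Overlapping-window definition and within-window agglomerative clustering.

Distances between methylation profiles use a masked Hamming distance: the
mean absolute difference over bins observed in both profiles, defined as 0
when the observed supports are disjoint. On binary profiles this reduces to
the Hamming fraction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .types import BinnedReadMatrix, Window, WindowClustering

logger = logging.getLogger(__name__)


def masked_distance(
    u: np.ndarray, v: np.ndarray, disjoint_distance: float = 0.0
) -> float:
    """Masked Hamming distance between two profiles with NaN missing values.

    d(u, v) = sum_i m_i |u_i - v_i| / sum_i m_i with m_i = 1 iff both
    entries are observed; returns ``disjoint_distance`` (default 0, per the
    published formula) when no bin is co-observed.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    m = ~np.isnan(u) & ~np.isnan(v)
    n = int(m.sum())
    if n == 0:
        return float(disjoint_distance)
    return float(np.abs(u[m] - v[m]).sum() / n)


def pairwise_masked_distance(
    X: np.ndarray, disjoint_distance: float = 0.0
) -> np.ndarray:
    """All-pairs masked Hamming distance for the rows of ``X`` (NaN = missing)."""
    X = np.asarray(X, dtype=float)
    obs = ~np.isnan(X)
    filled = np.nan_to_num(X)
    # (n, n, b) broadcast; window matrices are small enough
    both = obs[:, None, :] & obs[None, :, :]
    diff = np.abs(filled[:, None, :] - filled[None, :, :])
    num = np.where(both, diff, 0.0).sum(axis=2)
    den = both.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = num / den
    D[den == 0] = disjoint_distance
    np.fill_diagonal(D, 0.0)
    return D


def cross_masked_distance(
    A: np.ndarray, B: np.ndarray, disjoint_distance: float = 0.0
) -> np.ndarray:
    """Masked Hamming distances between rows of ``A`` and rows of ``B``."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must have the same number of bins")
    obs_a, obs_b = ~np.isnan(A), ~np.isnan(B)
    fa, fb = np.nan_to_num(A), np.nan_to_num(B)
    both = obs_a[:, None, :] & obs_b[None, :, :]
    diff = np.abs(fa[:, None, :] - fb[None, :, :])
    num = np.where(both, diff, 0.0).sum(axis=2)
    den = both.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = num / den
    D[den == 0] = disjoint_distance
    return D


def valid_bins(matrix: BinnedReadMatrix) -> np.ndarray:
    """Indices of bins covered by at least one read with methylation data."""
    return np.flatnonzero(matrix.observed.any(axis=0))


def define_windows(
    matrix: BinnedReadMatrix,
    window_size: int = 60,
    overlap: int = 20,
) -> list[Window]:
    """Tile the valid bins with overlapping windows.

    Windows hold ``window_size`` consecutive valid bins and advance with
    stride ``window_size - overlap``; the final window is right-anchored on
    the last valid bin so that it overlaps its predecessor by at least
    ``overlap`` bins. With fewer than ``window_size`` valid bins a single
    truncated window is returned with a warning.
    """
    if overlap >= window_size:
        raise ValueError("overlap must be smaller than window_size")
    vb = valid_bins(matrix)
    nv = len(vb)
    if nv == 0:
        raise ValueError("no valid bins: no read has methylation data")
    if nv < window_size:
        warnings.warn(
            f"only {nv} valid bins (< window size {window_size}); "
            "using a single truncated window",
            stacklevel=2,
        )
        return [Window(index=0, valid_bin_indices=vb)]
    stride = window_size - overlap
    starts = list(range(0, nv - window_size + 1, stride))
    if starts[-1] + window_size < nv:
        starts.append(nv - window_size)
    return [
        Window(index=i, valid_bin_indices=vb[s : s + window_size])
        for i, s in enumerate(starts)
    ]


def window_members(
    matrix: BinnedReadMatrix, window: Window, min_read_valid_bins: int = 30
) -> np.ndarray:
    """Rows with at least ``min_read_valid_bins`` observed bins in the window."""
    sub = matrix.observed[:, window.valid_bin_indices]
    return np.flatnonzero(sub.sum(axis=1) >= min_read_valid_bins)


def agglomerative_cluster(
    X: np.ndarray | None,
    t: int,
    D: np.ndarray | None = None,
    disjoint_distance: float = 0.0,
) -> np.ndarray:
    """Average-linkage agglomerative clustering down to ``t`` clusters.

    Starts from singletons and repeatedly merges the closest pair of
    clusters; after merging C_r and C_s, distances to every other cluster
    C_k are updated as

        d(C_rs, C_k) = (|C_r| d(C_r, C_k) + |C_s| d(C_s, C_k)) / (|C_r| + |C_s|)

    which is taken as the definition (it coincides with the mean of all
    pairwise distances on complete data). Ties are broken by merging the
    pair whose (smallest original member, largest cluster representative)
    key is lexicographically smallest, making the result deterministic.

    Either raw profiles ``X`` (NaN missing) or a precomputed distance
    matrix ``D`` may be given. Returns labels 0..t-1 ordered by each
    cluster's smallest member row. If fewer than ``t`` points are given,
    every point is its own cluster (with a warning).
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if D is None:
        if X is None:
            raise ValueError("provide either profiles X or a distance matrix D")
        D = pairwise_masked_distance(np.atleast_2d(X), disjoint_distance)
    else:
        D = np.asarray(D, dtype=float).copy()
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("D must be square")
    n = D.shape[0]
    if n < t:
        warnings.warn(
            f"{n} reads < t={t}; returning singleton clusters", stacklevel=2
        )
    if n <= t:
        return np.arange(n)

    work = D.copy()
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    # representative = smallest original row in the cluster (the slot index,
    # since we always merge into the smaller slot)
    members: list[list[int]] = [[i] for i in range(n)]
    n_clusters = n
    while n_clusters > t:
        masked = np.where(active[:, None] & active[None, :], work, np.inf)
        dmin = masked.min()
        ties = np.argwhere(masked == dmin)
        # each pair appears twice (i,j)/(j,i); normalize and pick lexic. min
        pairs = {(min(i, j), max(i, j)) for i, j in ties}
        r, s = min(pairs)
        # Lance-Williams average-linkage update into slot r
        new_row = (sizes[r] * work[r] + sizes[s] * work[s]) / (sizes[r] + sizes[s])
        work[r, :] = new_row
        work[:, r] = new_row
        work[r, r] = np.inf
        active[s] = False
        sizes[r] += sizes[s]
        members[r].extend(members[s])
        n_clusters -= 1

    slots = sorted(np.flatnonzero(active), key=lambda i: members[i][0])
    labels = np.empty(n, dtype=int)
    for label, slot in enumerate(slots):
        labels[members[slot]] = label
    return labels


def cluster_means(X: np.ndarray, labels: np.ndarray, t: int) -> np.ndarray:
    """Per-cluster mean profile over observed member entries (NaN if none)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = np.full((t, X.shape[1]), np.nan)
    for k in range(t):
        rows = X[labels == k]
        if rows.size == 0:
            logger.warning("cluster %d is empty; mean profile is all-missing", k)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu[k] = np.nanmean(rows, axis=0)
    return mu


def cluster_window(
    matrix: BinnedReadMatrix,
    window: Window,
    t: int,
    min_read_valid_bins: int = 30,
    disjoint_distance: float = 0.0,
) -> WindowClustering:
    """Cluster the reads of one window into ``t`` clusters."""
    rows = window_members(matrix, window, min_read_valid_bins)
    sub = matrix.values[np.ix_(rows, window.valid_bin_indices)]
    if len(rows) == 0:
        labels = np.empty(0, dtype=int)
    else:
        labels = agglomerative_cluster(sub, t, disjoint_distance=disjoint_distance)
    mu = cluster_means(sub, labels, t)
    return WindowClustering(window=window, member_rows=rows, labels=labels, mu=mu, t=t)


def silhouette_sweep(
    matrix: BinnedReadMatrix,
    window: Window,
    t_values: list[int],
    min_read_valid_bins: int = 30,
) -> dict[int, float]:
    """Extension helper: mean silhouette under the masked distance per t."""
    from sklearn.metrics import silhouette_score

    rows = window_members(matrix, window, min_read_valid_bins)
    sub = matrix.values[np.ix_(rows, window.valid_bin_indices)]
    D = pairwise_masked_distance(sub)
    out: dict[int, float] = {}
    for t in t_values:
        if not 2 <= t < len(rows):
            continue
        labels = agglomerative_cluster(None, t, D=D)
        out[t] = float(silhouette_score(D, labels, metric="precomputed"))
    return out
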