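"""Global reassignment of reads to stitched cluster series."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import UNASSIGNED, BinnedReadMatrix, ClusterSeries
from .stitch import recompute_profiles, series_profiles
from .window_cluster import cross_masked_distance

logger = logging.getLogger(__name__)


def assign_global(
    matrix: BinnedReadMatrix,
    series: list[ClusterSeries] | np.ndarray,
) -> pd.DataFrame:
    """Assign each read to its most similar series by masked Hamming distance.

    Ties go to the lowest series id. Reads sharing no observed bin with any
    series are UNASSIGNED. Returns a DataFrame with columns ``read_id,
    label, distance, n_shared_bins``; labels are series-id strings.
    """
    if not isinstance(series, np.ndarray) and len(series) == 0:
        raise ValueError("no series to assign to")
    profiles = (
        series if isinstance(series, np.ndarray) else series_profiles(series)
    )
    if profiles.shape[0] == 0:
        raise ValueError("no series to assign to")
    if matrix.n_reads == 0:
        return pd.DataFrame(
            columns=["read_id", "label", "distance", "n_shared_bins"]
        )
    obs_r = matrix.observed
    obs_s = ~np.isnan(profiles)
    shared = obs_r.astype(np.int32) @ obs_s.T.astype(np.int32)  # (n, t)
    # disjoint-support pairs are excluded from the argmin rather than scored 0
    D = cross_masked_distance(matrix.values, profiles)
    D = np.where(shared > 0, D, np.inf)
    best = D.argmin(axis=1)  # argmin takes the first (lowest id) on ties
    best_d = D[np.arange(matrix.n_reads), best]
    orphan = ~np.isfinite(best_d)

    labels = best.astype(object)
    labels[orphan] = UNASSIGNED
    out = pd.DataFrame(
        {
            "read_id": matrix.read_ids,
            "label": [str(x) for x in labels],
            "distance": np.where(orphan, np.nan, best_d),
            "n_shared_bins": shared[np.arange(matrix.n_reads), best],
        }
    )
    out.loc[orphan, "n_shared_bins"] = 0
    if orphan.any():
        logger.info("%d read(s) share no bins with any series", int(orphan.sum()))
    return out


def _labels_array(assignments: pd.DataFrame, matrix: BinnedReadMatrix) -> np.ndarray:
    lab = np.full(matrix.n_reads, -1, dtype=int)
    by_read = dict(zip(assignments["read_id"], assignments["label"]))
    for i, rid in enumerate(matrix.read_ids):
        val = by_read.get(rid, UNASSIGNED)
        if val != UNASSIGNED:
            lab[i] = int(val)
    return lab


def reassign_iterate(
    matrix: BinnedReadMatrix,
    assignments: pd.DataFrame,
    t: int,
    max_iter: int = 1,
) -> pd.DataFrame:
    """Optional refinement: alternate profile recomputation and reassignment.

    Stops at ``max_iter`` passes or when the assignment is a fixed point.
    The total within-series masked distance is non-increasing.
    """
    if max_iter < 0:
        raise ValueError("max_iter must be >= 0")
    current = assignments
    for _ in range(max_iter):
        labels = _labels_array(current, matrix)
        profiles = recompute_profiles(matrix, labels, t)
        nxt = assign_global(matrix, profiles)
        if nxt["label"].tolist() == current["label"].tolist():
            return nxt
        current = nxt
    return current


def series_summary(
    assignments: pd.DataFrame,
    matrix: BinnedReadMatrix,
    t: int,
    recompute: bool = True,
    series: list[ClusterSeries] | None = None,
) -> dict:
    """Per-series read counts, proportions and (optionally refreshed) profiles.

    Proportions are over assigned (non-UNASSIGNED) reads and sum to 1.
    """
    counts = {k: 0 for k in range(t)}
    for lab in assignments["label"]:
        if lab != UNASSIGNED:
            counts[int(lab)] += 1
    n_assigned = sum(counts.values())
    proportions = {
        k: (counts[k] / n_assigned if n_assigned else float("nan"))
        for k in range(t)
    }
    if recompute:
        labels = _labels_array(assignments, matrix)
        profiles = recompute_profiles(matrix, labels, t)
        occupancy = np.vstack(
            [matrix.observed[labels == k].sum(axis=0) for k in range(t)]
        )
    else:
        if series is None:
            raise ValueError("series required when recompute=False")
        profiles = series_profiles(series)
        occupancy = None
    return {
        "counts": counts,
        "proportions": proportions,
        "n_assigned": n_assigned,
        "n_unassigned": int((assignments["label"] == UNASSIGNED).sum()),
        "profiles": profiles,
        "occupancy": occupancy,
    }
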