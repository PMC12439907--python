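"""Read filtering, 50-bp binning, smoothing and extreme-read pre-assignment."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import FULLY_METH, FULLY_UNMETH, BinGrid, BinnedReadMatrix, RegionSpec

logger = logging.getLogger(__name__)


def filter_reads(
    calls: pd.DataFrame,
    min_span: int = 10,
    min_gpc: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-quality or uninformative molecules.

    A read is dropped when its reference span (last - first call position,
    half-open) is below ``min_span`` bp or it carries fewer than ``min_gpc``
    calls. Returns (retained calls, exclusion log with one row per dropped
    read and the reason).
    """
    if calls.empty:
        log = pd.DataFrame(columns=["read_id", "reason", "span", "n_gpc"])
        return calls, log

    grouped = calls.groupby("read_id", sort=True)["position"]
    stats = grouped.agg(first="min", last="max", n_gpc="size")
    stats["span"] = stats["last"] - stats["first"] + 1

    too_short = stats["span"] < min_span
    too_few = stats["n_gpc"] < min_gpc
    dropped = stats[too_short | too_few]
    reasons = np.where(
        too_short[dropped.index], f"span<{min_span}", f"n_gpc<{min_gpc}"
    )
    log = pd.DataFrame(
        {
            "read_id": dropped.index,
            "reason": reasons,
            "span": dropped["span"].to_numpy(),
            "n_gpc": dropped["n_gpc"].to_numpy(),
        }
    ).reset_index(drop=True)

    retained = calls[~calls["read_id"].isin(set(dropped.index))].reset_index(
        drop=True
    )
    if len(log):
        logger.info("filtered out %d read(s)", len(log))
    return retained, log


def make_grid(
    calls: pd.DataFrame, region: RegionSpec, bin_width: int = 50
) -> BinGrid:
    """Bin grid spanning from the first call to the last call, clipped to region."""
    if calls.empty:
        raise ValueError("cannot build a grid from an empty call table")
    first = int(calls["position"].min())
    last = int(calls["position"].max()) + 1
    origin = max(region.start, first)
    stop = min(region.end, last)
    return BinGrid(region=region, bin_width=bin_width, origin=origin, stop=stop)


def bin_reads(calls: pd.DataFrame, grid: BinGrid) -> BinnedReadMatrix:
    """Average binary calls per read into the grid's fixed-width bins.

    Each bin value is the mean of the read's calls falling in the bin; bins
    with no calls are missing (NaN).
    """
    if calls.empty:
        return BinnedReadMatrix(grid=grid, read_ids=[], values=np.empty((0, grid.n_bins)))
    pos = calls["position"].to_numpy()
    inside = grid.contains(pos)
    if not np.all(inside):
        bad = pos[~inside][0]
        raise ValueError(
            f"call at position {bad} falls outside grid [{grid.origin}, {grid.stop})"
        )
    read_ids = sorted(calls["read_id"].unique())
    row_of = {rid: i for i, rid in enumerate(read_ids)}
    rows = calls["read_id"].map(row_of).to_numpy()
    cols = grid.bin_index(pos)
    vals = calls["call"].to_numpy(dtype=float)

    shape = (len(read_ids), grid.n_bins)
    sums = np.zeros(shape)
    counts = np.zeros(shape)
    np.add.at(sums, (rows, cols), vals)
    np.add.at(counts, (rows, cols), 1.0)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedReadMatrix(grid=grid, read_ids=list(read_ids), values=values)


def bin_single_read(
    calls: pd.DataFrame, grid: BinGrid, read_id: str
) -> np.ndarray:
    """Bin one read's calls on an existing grid, dropping out-of-grid calls.

    Used to project a held-out read onto a grid built without it.
    """
    sub = calls[calls["read_id"] == read_id]
    sub = sub[grid.contains(sub["position"].to_numpy())]
    vec = np.full(grid.n_bins, np.nan)
    if sub.empty:
        return vec
    cols = grid.bin_index(sub["position"].to_numpy())
    sums = np.bincount(cols, weights=sub["call"].to_numpy(dtype=float), minlength=grid.n_bins)
    counts = np.bincount(cols, minlength=grid.n_bins)
    np.divide(sums, counts, out=vec, where=counts > 0)
    return vec


def smooth(matrix: BinnedReadMatrix, half_window: int = 1) -> BinnedReadMatrix:
    """Masked rolling mean over +/- ``half_window`` bins per read.

    Missing entries stay missing; observed entries become the mean of
    observed neighbours within the window. ``half_window=0`` is the identity.
    """
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    if half_window == 0 or matrix.n_reads == 0:
        return BinnedReadMatrix(matrix.grid, list(matrix.read_ids), matrix.values.copy())

    obs = matrix.observed
    filled = np.nan_to_num(matrix.values)
    kernel = np.ones(2 * half_window + 1)
    sums = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same"), 1, filled
    )
    counts = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same"), 1, obs.astype(float)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[~obs] = np.nan
    return BinnedReadMatrix(matrix.grid, list(matrix.read_ids), out)


def preassign_extremes(
    matrix: BinnedReadMatrix, theta: float = 0.95
) -> tuple[dict[str, str], BinnedReadMatrix]:
    """Pre-assign fully methylated / fully unmethylated molecules.

    Reads whose mean observed bin value is >= ``theta`` are labeled
    FULLY_METH, <= 1 - theta FULLY_UNMETH; both are removed from the
    returned clustering matrix.
    """
    if not 0.5 < theta <= 1.0:
        raise ValueError("theta must lie in (0.5, 1]")
    if matrix.n_reads == 0:
        return {}, matrix
    with np.errstate(invalid="ignore"):
        means = np.nanmean(matrix.values, axis=1)
    labels: dict[str, str] = {}
    keep = np.ones(matrix.n_reads, dtype=bool)
    for i, (rid, m) in enumerate(zip(matrix.read_ids, means)):
        if not np.isfinite(m):
            continue
        if m >= theta:
            labels[rid] = FULLY_METH
            keep[i] = False
        elif m <= 1.0 - theta:
            labels[rid] = FULLY_UNMETH
            keep[i] = False
    reduced = matrix.subset(np.flatnonzero(keep))
    if labels:
        logger.info("pre-assigned %d extreme read(s)", len(labels))
    return labels, reduced
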