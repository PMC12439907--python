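"""End-to-end phasing: filter -> bin -> window-cluster -> stitch -> reassign."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PhasingConfig
from .phase import assign_global, reassign_iterate, series_summary
from .preprocess import bin_reads, filter_reads, make_grid, preassign_extremes, smooth
from .stitch import stitch_all
from .types import UNASSIGNED, BinnedReadMatrix, PhasingResultBundle, RegionSpec
from .window_cluster import cluster_window, define_windows

logger = logging.getLogger(__name__)


def phase_region(
    calls: pd.DataFrame,
    region: RegionSpec,
    t: int,
    config: PhasingConfig | None = None,
    seed: int | None = None,
    debug: bool = False,
) -> PhasingResultBundle:
    """Run the full cluster-based phasing pipeline on one region.

    ``calls`` is a canonical call table (see :func:`nomephase.io.read_calls`).
    Every input read appears exactly once in the returned assignments:
    reads failing the quality filters are UNASSIGNED, extreme reads carry
    their FULLY_METH / FULLY_UNMETH label, the rest a series id.
    """
    cfg = config or PhasingConfig()
    cfg.validate()
    if t < 1:
        raise ValueError("t must be >= 1")

    all_read_ids = sorted(calls["read_id"].unique())
    counts: dict[str, int] = {"input_reads": len(all_read_ids)}

    retained, exclusion_log = filter_reads(
        calls, min_span=cfg.min_read_span, min_gpc=cfg.min_gpc
    )
    counts["filtered_out"] = len(exclusion_log)
    if retained.empty:
        raise ValueError("no reads left after quality filtering")

    grid = make_grid(retained, region, cfg.bin_width)
    matrix = bin_reads(retained, grid)
    if cfg.smooth_half_window and cfg.smooth_for_clustering:
        matrix = smooth(matrix, cfg.smooth_half_window)

    extreme_labels, clus_matrix = preassign_extremes(matrix, cfg.extreme_theta)
    counts["fully_methylated"] = sum(
        1 for v in extreme_labels.values() if v == "FULLY_METH"
    )
    counts["fully_unmethylated"] = sum(
        1 for v in extreme_labels.values() if v == "FULLY_UNMETH"
    )
    counts["clusterable"] = clus_matrix.n_reads
    if clus_matrix.n_reads == 0:
        raise ValueError("no clusterable reads (all filtered or pre-assigned)")

    windows = define_windows(clus_matrix, cfg.window_size, cfg.window_overlap)
    counts["windows"] = len(windows)
    clusterings = [
        cluster_window(
            clus_matrix,
            w,
            t,
            min_read_valid_bins=cfg.min_read_valid_bins,
            disjoint_distance=cfg.disjoint_distance,
        )
        for w in windows
    ]
    series, diagnostics = stitch_all(
        clusterings,
        grid.n_bins,
        disjoint_distance=cfg.disjoint_distance,
        collect_diagnostics=debug,
    )

    assignments = assign_global(clus_matrix, series)
    if cfg.reassign_iters:
        assignments = reassign_iterate(
            clus_matrix, assignments, t, max_iter=cfg.reassign_iters
        )

    summary = series_summary(assignments, clus_matrix, t, recompute=True)
    for s in series:
        s.n_members = summary["counts"][s.series_id]
        # report profiles recomputed from the final membership
        s.profile = summary["profiles"][s.series_id]

    rows = [assignments]
    if extreme_labels:
        rows.append(
            pd.DataFrame(
                {
                    "read_id": list(extreme_labels),
                    "label": list(extreme_labels.values()),
                    "distance": np.nan,
                    "n_shared_bins": 0,
                }
            )
        )
    dropped_ids = sorted(set(all_read_ids) - set(retained["read_id"]))
    if dropped_ids:
        rows.append(
            pd.DataFrame(
                {
                    "read_id": dropped_ids,
                    "label": UNASSIGNED,
                    "distance": np.nan,
                    "n_shared_bins": 0,
                }
            )
        )
    table = (
        pd.concat(rows, ignore_index=True)
        .sort_values("read_id", kind="mergesort")
        .reset_index(drop=True)
    )
    assert len(table) == len(all_read_ids), "assignment table must cover all reads"

    counts["assigned"] = summary["n_assigned"]
    counts["unassigned"] = int((table["label"] == UNASSIGNED).sum())
    metadata = {
        "region": str(region),
        "t": t,
        "seed": seed,
        "parameters": cfg.to_dict(),
        "stage_counts": counts,
        "series_proportions": summary["proportions"],
        "exclusion_reasons": exclusion_log["reason"].value_counts().to_dict()
        if len(exclusion_log)
        else {},
    }
    if debug:
        metadata["stitch_diagnostics"] = diagnostics

    bundle = PhasingResultBundle(
        region=region,
        grid=grid,
        assignments=table,
        series=series,
        metadata=metadata,
    )
    bundle.clustering_matrix = clus_matrix  # kept for validation / scoring
    bundle.full_matrix = matrix
    return bundle
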