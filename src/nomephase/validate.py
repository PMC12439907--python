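"""Leave-one-out long-read accuracy of the cluster-based phasing.

A qualifying long read is held out, the locus is phased without it, the
held-out read is binned on the resulting grid and compared to every
stitched series profile; its accuracy is

    A(r) = 1 - min_j d_H(r, series_j)

and the overall clustering accuracy is the mean of A over all evaluated
long reads.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PhasingConfig
from .pipeline import phase_region
from .preprocess import bin_single_read
from .stitch import series_profiles
from .types import AccuracyRecord, AccuracyReport, RegionSpec

logger = logging.getLogger(__name__)

DEFAULT_MIN_LONG_LENGTH = 50_000


def find_long_reads(
    calls: pd.DataFrame, min_long_length: int = DEFAULT_MIN_LONG_LENGTH
) -> list[str]:
    """Read ids whose call span is at least ``min_long_length`` bp."""
    if calls.empty:
        return []
    span = calls.groupby("read_id")["position"].agg(lambda p: p.max() - p.min() + 1)
    return sorted(span[span >= min_long_length].index)


def evaluate_long_read(
    calls: pd.DataFrame,
    region: RegionSpec,
    long_read_id: str,
    t: int,
    config: PhasingConfig | None = None,
    locus_id: str = "locus",
) -> AccuracyRecord:
    """Hold out one long read, phase the rest and score the held-out read.

    The grid, valid bins and windows are recomputed strictly without the
    held-out read (no leakage); the read is then binned on that grid,
    clipping any calls falling outside it.
    """
    own = calls[calls["read_id"] == long_read_id]
    if own.empty:
        raise ValueError(f"read {long_read_id!r} not present in the call table")
    read_length = int(own["position"].max() - own["position"].min() + 1)
    rest = calls[calls["read_id"] != long_read_id].reset_index(drop=True)

    bundle = phase_region(rest, region, t, config=config)
    vec = bin_single_read(calls, bundle.grid, long_read_id)
    profiles = series_profiles(bundle.series)

    obs = ~np.isnan(vec)
    shared = (obs[None, :] & ~np.isnan(profiles)).sum(axis=1)
    if not (shared > 0).any():
        return AccuracyRecord(
            locus_id=locus_id,
            read_id=long_read_id,
            read_length=read_length,
            best_series_id=None,
            accuracy=float("nan"),
            n_shared_bins=0,
            error="held-out read shares no observed bins with any series",
        )
    dists = np.array(
        [
            _masked(vec, profiles[k]) if shared[k] > 0 else np.inf
            for k in range(profiles.shape[0])
        ]
    )
    best = int(dists.argmin())
    return AccuracyRecord(
        locus_id=locus_id,
        read_id=long_read_id,
        read_length=read_length,
        best_series_id=best,
        accuracy=float(1.0 - dists[best]),
        n_shared_bins=int(shared[best]),
    )


def _masked(u: np.ndarray, v: np.ndarray) -> float:
    m = ~np.isnan(u) & ~np.isnan(v)
    return float(np.abs(u[m] - v[m]).mean())


def evaluate_many(
    loci: list[dict],
    t: int,
    config: PhasingConfig | None = None,
    min_long_length: int = DEFAULT_MIN_LONG_LENGTH,
) -> AccuracyReport:
    """Aggregate leave-one-out accuracy over several loci.

    Each locus is a dict with keys ``locus_id``, ``calls`` (DataFrame),
    ``region`` and optionally ``long_read_ids`` (otherwise every read
    spanning at least ``min_long_length`` is evaluated). Loci without a
    qualifying read or failing coverage are reported as skipped.
    """
    records: list[AccuracyRecord] = []
    skipped: list[tuple[str, str]] = []
    for locus in loci:
        locus_id = locus["locus_id"]
        calls = locus["calls"]
        region = locus["region"]
        long_ids = locus.get("long_read_ids") or find_long_reads(
            calls, min_long_length
        )
        if not long_ids:
            skipped.append((locus_id, "no qualifying long read"))
            continue
        for rid in long_ids:
            try:
                rec = evaluate_long_read(
                    calls, region, rid, t, config=config, locus_id=locus_id
                )
            except ValueError as exc:
                skipped.append((locus_id, f"{rid}: {exc}"))
                continue
            records.append(rec)
    return AccuracyReport(records=records, skipped=skipped)


def report_to_frame(report: AccuracyReport) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in report.records],
            "read_id": [r.read_id for r in report.records],
            "read_length": [r.read_length for r in report.records],
            "best_series_id": [r.best_series_id for r in report.records],
            "accuracy": [r.accuracy for r in report.records],
            "n_shared_bins": [r.n_shared_bins for r in report.records],
        }
    )
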