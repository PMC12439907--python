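"""Reading per-read methylation call tables and writing phasing artifacts.

The canonical input is a tab-separated table with one row per GpC call,
modeled on ``modkit extract`` output: read identifier, contig, reference
position (0-based), strand, call (methylated / unmethylated) and call
confidence. Column names are configurable; common synonyms are recognized
out of the box.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import PhasingResultBundle, RegionSpec

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("read_id", "contig", "position", "strand", "call")

#: recognized header synonyms, canonical name -> aliases (lower-cased match)
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "read_id": ("read_id", "read_name", "readname", "query_name", "read"),
    "contig": ("contig", "chrom", "chromosome", "chr", "ref", "#chromosome"),
    "position": ("position", "pos", "ref_position", "start", "forward_read_position"),
    "strand": ("strand", "ref_strand"),
    "call": ("call", "call_code", "mod_call", "status", "mod"),
    "confidence": ("confidence", "call_prob", "probability", "prob", "qual"),
}

_METH_TOKENS = {"m", "meth", "methylated", "mod", "modified", "1", "true"}
_UNMETH_TOKENS = {"u", "unmeth", "unmethylated", "-", "c", "canonical", "0", "false"}


class CallTableFormatError(ValueError):
    """Raised when the input table does not match the expected schema."""


def _resolve_columns(
    header: list[str], column_map: dict[str, str] | None
) -> dict[str, str]:
    """Map canonical column names to actual header names."""
    lowered = {col.lower(): col for col in header}
    resolved: dict[str, str] = {}
    explicit = column_map or {}
    for canonical, aliases in COLUMN_SYNONYMS.items():
        if canonical in explicit:
            if explicit[canonical] not in header:
                raise CallTableFormatError(
                    f"mapped column {explicit[canonical]!r} for {canonical!r} "
                    f"not found in header {header}"
                )
            resolved[canonical] = explicit[canonical]
            continue
        for alias in aliases:
            if alias in lowered:
                resolved[canonical] = lowered[alias]
                break
    missing = [c for c in CANONICAL_COLUMNS if c not in resolved]
    if missing:
        raise CallTableFormatError(
            f"required column(s) {missing} not found in header {header}; "
            "pass column_map to name them explicitly"
        )
    return resolved


def _normalize_calls(raw: pd.Series) -> np.ndarray:
    tokens = raw.astype(str).str.strip().str.lower()
    meth = tokens.isin(_METH_TOKENS)
    unmeth = tokens.isin(_UNMETH_TOKENS)
    bad = ~(meth | unmeth)
    if bad.any():
        example = tokens[bad].iloc[0]
        raise CallTableFormatError(
            f"unrecognized call value {example!r}; expected one of "
            f"{sorted(_METH_TOKENS | _UNMETH_TOKENS)}"
        )
    return meth.to_numpy().astype(np.int8)


def read_calls(
    path: str | Path,
    region: RegionSpec | None = None,
    min_confidence: float = 0.0,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Load a per-read methylation call table.

    Returns a DataFrame with columns ``read_id, contig, position, strand,
    call, confidence`` (call coded 0/1), restricted to ``region`` (0-based,
    half-open) and to calls with confidence >= ``min_confidence``, sorted by
    (read_id, position). Counts of rows dropped at each step are stored in
    ``df.attrs["filter_counts"]``.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    cols = _resolve_columns(list(raw.columns), column_map)

    df = pd.DataFrame(
        {
            "read_id": raw[cols["read_id"]].astype(str),
            "contig": raw[cols["contig"]].astype(str),
            "position": pd.to_numeric(raw[cols["position"]]).astype(np.int64),
            "strand": raw[cols["strand"]].astype(str),
            "call": _normalize_calls(raw[cols["call"]]),
        }
    )
    if "confidence" in cols:
        df["confidence"] = pd.to_numeric(raw[cols["confidence"]]).astype(float)
        if ((df["confidence"] < 0) | (df["confidence"] > 1)).any():
            raise CallTableFormatError("confidence values must lie in [0, 1]")
    else:
        df["confidence"] = 1.0

    counts = {"input_rows": int(len(df))}
    if region is not None:
        in_region = (
            (df["contig"] == region.contig)
            & (df["position"] >= region.start)
            & (df["position"] < region.end)
        )
        counts["outside_region"] = int((~in_region).sum())
        df = df[in_region]
    low_conf = df["confidence"] < min_confidence
    counts["below_confidence"] = int(low_conf.sum())
    if counts["below_confidence"]:
        logger.info(
            "dropped %d call(s) below confidence %.3g",
            counts["below_confidence"],
            min_confidence,
        )
    df = df[~low_conf]

    df = df.sort_values(["read_id", "position"], kind="mergesort").reset_index(
        drop=True
    )
    dup = df.duplicated(subset=["read_id", "contig", "position"])
    if dup.any():
        raise CallTableFormatError(
            f"{int(dup.sum())} duplicate (read_id, contig, position) row(s)"
        )
    counts["retained_rows"] = int(len(df))
    df.attrs["filter_counts"] = counts
    return df


def write_calls(df: pd.DataFrame, path: str | Path) -> None:
    """Write a call table in the canonical TSV dialect."""
    out = df.copy()
    out["call"] = np.where(out["call"].astype(int) == 1, "m", "u")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_assignments(bundle: PhasingResultBundle, prefix: str | Path) -> list[Path]:
    """Write the phasing artifacts for one run.

    Produces ``<prefix>.assignments.tsv`` (read -> label), one
    ``<prefix>.series_<k>.bedgraph`` per stitched series (per-bin mean
    methylation) and ``<prefix>.report.json`` (parameter echo, seed and
    per-stage read counts). Returns the written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    tsv_path = prefix.with_name(prefix.name + ".assignments.tsv")
    out = bundle.assignments.copy()
    out["distance"] = [
        "" if not np.isfinite(d) else f"{d:.10g}" for d in out["distance"]
    ]
    out.to_csv(tsv_path, sep="\t", index=False)
    paths.append(tsv_path)

    grid = bundle.grid
    starts, ends = grid.bin_starts, grid.bin_ends
    for series in bundle.series:
        bg_path = prefix.with_name(f"{prefix.name}.series_{series.series_id}.bedgraph")
        with open(bg_path, "w") as fh:
            for b in np.flatnonzero(np.isfinite(series.profile)):
                fh.write(
                    f"{grid.region.contig}\t{starts[b]}\t{ends[b]}\t"
                    f"{series.profile[b]:.6g}\n"
                )
        paths.append(bg_path)

    report_path = prefix.with_name(prefix.name + ".report.json")
    with open(report_path, "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    paths.append(report_path)
    return paths


def read_assignments(path: str | Path) -> pd.DataFrame:
    """Re-read an assignments TSV written by :func:`write_assignments`."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "label": str})
    df["distance"] = pd.to_numeric(df["distance"], errors="coerce")
    return df
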