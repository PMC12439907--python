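"""Core domain types shared across the phasing pipeline.

Coordinates are 0-based, half-open everywhere. Missing methylation values
are represented by ``numpy.nan`` in float arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Sentinel labels used in assignment tables.
FULLY_METH = "FULLY_METH"
FULLY_UNMETH = "FULLY_UNMETH"
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class RegionSpec:
    """A genomic region, 0-based half-open."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"region end ({self.end}) must be > start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse ``contig:start-end`` notation."""
        try:
            contig, coords = text.rsplit(":", 1)
            lo, hi = coords.replace(",", "").split("-")
            return cls(contig, int(lo), int(hi))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"cannot parse region {text!r}") from exc


@dataclass(frozen=True)
class BinGrid:
    """Uniform bin partition of a region stretch.

    Bins start at ``origin`` and tile to ``stop``; the last bin may be
    shorter than ``bin_width``.
    """

    region: RegionSpec
    bin_width: int
    origin: int
    stop: int

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not (self.region.start <= self.origin < self.stop <= self.region.end):
            raise ValueError(
                f"grid [{self.origin}, {self.stop}) must lie inside {self.region}"
            )

    @property
    def n_bins(self) -> int:
        return -(-(self.stop - self.origin) // self.bin_width)

    @property
    def bin_starts(self) -> np.ndarray:
        return self.origin + self.bin_width * np.arange(self.n_bins)

    @property
    def bin_ends(self) -> np.ndarray:
        ends = self.bin_starts + self.bin_width
        ends[-1] = min(ends[-1], self.stop)
        return ends

    def bin_index(self, position: np.ndarray | int) -> np.ndarray | int:
        """Map reference position(s) to bin index; caller checks bounds."""
        return (np.asarray(position) - self.origin) // self.bin_width

    def contains(self, position: np.ndarray | int) -> np.ndarray | bool:
        pos = np.asarray(position)
        return (pos >= self.origin) & (pos < self.stop)


@dataclass
class BinnedReadMatrix:
    """Reads x bins fractional-methylation matrix with NaN for MISSING."""

    grid: BinGrid
    read_ids: list[str]
    values: np.ndarray  # (n_reads, n_bins) float64, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.read_ids), self.grid.n_bins):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.read_ids)} reads x {self.grid.n_bins} bins"
            )

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_valid_bins(self) -> np.ndarray:
        """Per-read count of non-missing bins."""
        return self.observed.sum(axis=1)

    def subset(self, row_indices: np.ndarray) -> "BinnedReadMatrix":
        row_indices = np.asarray(row_indices)
        return BinnedReadMatrix(
            grid=self.grid,
            read_ids=[self.read_ids[i] for i in row_indices],
            values=self.values[row_indices],
        )


@dataclass
class Window:
    """A window of ``valid_bin_indices`` (indices into the grid)."""

    index: int
    valid_bin_indices: np.ndarray

    @property
    def size(self) -> int:
        return len(self.valid_bin_indices)

    @property
    def genomic_span(self) -> tuple[int, int]:
        return int(self.valid_bin_indices[0]), int(self.valid_bin_indices[-1]) + 1


@dataclass
class WindowClustering:
    """Per-window read partition plus cluster mean profiles mu."""

    window: Window
    member_rows: np.ndarray  # row indices into the clustering matrix
    labels: np.ndarray  # cluster id in 0..t-1 per member
    mu: np.ndarray  # (t, window.size), NaN where no member observed
    t: int

    @property
    def n_members(self) -> int:
        return len(self.member_rows)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.t)


@dataclass
class ClusterSeries:
    """A stitched chain of matched window clusters spanning the region."""

    series_id: int
    window_cluster_ids: list[int]  # one per window
    profile: np.ndarray  # (n_bins,) over the full grid, NaN = missing
    n_members: int = 0


@dataclass
class PhasingResultBundle:
    """Everything one phasing run produces."""

    region: RegionSpec
    grid: BinGrid
    assignments: Any  # pandas DataFrame: read_id, label, distance, n_shared_bins
    series: list[ClusterSeries]
    metadata: dict = field(default_factory=dict)


@dataclass
class AccuracyRecord:
    """Leave-one-out score for one held-out long read at one locus."""

    locus_id: str
    read_id: str
    read_length: int
    best_series_id: int | None
    accuracy: float  # A(r_i) = 1 - min_j d_H(r_i, series_j); NaN if undefined
    n_shared_bins: int = 0
    error: str | None = None


@dataclass
class AccuracyReport:
    records: list[AccuracyRecord]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (locus, reason)

    @property
    def overall(self) -> float:
        vals = [r.accuracy for r in self.records if np.isfinite(r.accuracy)]
        return float(np.mean(vals)) if vals else float("nan")
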