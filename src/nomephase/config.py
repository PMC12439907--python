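"""Run configuration with the published pipeline defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass
class PhasingConfig:
    """Parameters of the cluster-based phasing pipeline.

    Defaults follow the published method: 50 bp bins, 60-valid-bin windows
    overlapping by at least 20 bins, reads filtered at <10 bp span or
    <10 GpC calls, and a 30-valid-bin per-window membership filter.
    """

    bin_width: int = 50
    min_read_span: int = 10
    min_gpc: int = 10
    min_confidence: float = 0.0
    smooth_half_window: int = 1
    #: cluster on smoothed values instead of raw binned values
    smooth_for_clustering: bool = False
    extreme_theta: float = 0.95
    window_size: int = 60
    window_overlap: int = 20
    min_read_valid_bins: int = 30
    #: distance assigned to vector pairs with no co-observed bin (the
    #: published formula uses 0; set to 1.0 to penalize disjoint supports)
    disjoint_distance: float = 0.0
    #: extra profile-recompute/reassign passes after the global assignment
    reassign_iters: int = 0

    def validate(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not 0.5 < self.extreme_theta <= 1.0:
            raise ValueError("extreme_theta must be in (0.5, 1]")
        if self.window_overlap >= self.window_size:
            raise ValueError("window_overlap must be < window_size")
        if self.smooth_half_window < 0:
            raise ValueError("smooth_half_window must be >= 0")
        if self.disjoint_distance not in (0.0, 1.0):
            raise ValueError("disjoint_distance must be 0.0 or 1.0")
        if self.reassign_iters < 0:
            raise ValueError("reassign_iters must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "PhasingConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        cfg.validate()
        return cfg
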