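import numpy as np
import pandas as pd
import pytest

from nomephase.config import PhasingConfig
from nomephase.simulate import SimConfig, default_states, simulate_locus
from nomephase.types import BinGrid, BinnedReadMatrix, RegionSpec

NAN = float("nan")


def calls_frame(rows):
    """Build a canonical call table from (read_id, position, call) tuples."""
    df = pd.DataFrame(rows, columns=["read_id", "position", "call"])
    df["contig"] = "chr1"
    df["strand"] = "+"
    df["confidence"] = 1.0
    return df[["read_id", "contig", "position", "strand", "call", "confidence"]]


def matrix_from_values(values, bin_width=50, contig="chr1"):
    """BinnedReadMatrix directly from a (n_reads, n_bins) array (NaN missing)."""
    values = np.asarray(values, dtype=float)
    n_bins = values.shape[1]
    region = RegionSpec(contig, 0, n_bins * bin_width)
    grid = BinGrid(region=region, bin_width=bin_width, origin=0, stop=region.end)
    return BinnedReadMatrix(
        grid=grid,
        read_ids=[f"r{i}" for i in range(values.shape[0])],
        values=values,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_locus():
    """Default-parameter 3-state simulated locus (noisy, fragmented)."""
    cfg = SimConfig(seed=11)
    states = default_states(3, cfg.locus_length, seed=12)
    table, truth = simulate_locus(cfg, states)
    region = RegionSpec(cfg.contig, 0, cfg.locus_length)
    return table, truth, region


@pytest.fixture(scope="session")
def sim_locus_clean():
    """Noise-free fragmented 3-state locus."""
    cfg = SimConfig(seed=11, p_fail_meth=0.0, p_spurious_meth=0.0, p_call_drop=0.0)
    states = default_states(3, cfg.locus_length, seed=12)
    table, truth = simulate_locus(cfg, states)
    region = RegionSpec(cfg.contig, 0, cfg.locus_length)
    return table, truth, region


@pytest.fixture(scope="session")
def small_sim_locus():
    """Small fast locus (12 kb) for CLI / phase-level tests."""
    cfg = SimConfig(
        locus_length=12_000,
        median_read_length=3_000,
        coverage=40.0,
        n_long_reads=1,
        seed=7,
    )
    states = default_states(2, cfg.locus_length, seed=8)
    table, truth = simulate_locus(cfg, states)
    region = RegionSpec(cfg.contig, 0, cfg.locus_length)
    return table, truth, region


@pytest.fixture
def default_config():
    return PhasingConfig()
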