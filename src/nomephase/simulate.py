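"""Synthetic nano-NOMe-seq locus generator with known latent structure.

Each latent accessibility state is an interval tiling of the locus into
nucleosomes (147 bp, protected), linkers (accessible), nucleosome-free
regions (150-400 bp, accessible) and TF footprints (35-50 bp, protected,
inside an NFR). Molecules draw a state, a start and a length, and emit one
call per covered GpC site: methylated iff the site is accessible, then
corrupted by asymmetric noise and random call dropping. A configurable
number of long reads spans the entire locus so that window stitching and
leave-one-out validation can be exercised with ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .types import UNASSIGNED

NUCLEOSOME_BP = 147

#: interval kinds considered accessible (GpC methylated in a perfect assay)
ACCESSIBLE_KINDS = frozenset({"linker", "nfr"})
PROTECTED_KINDS = frozenset({"nucleosome", "tf"})


@dataclass(frozen=True)
class Interval:
    start: int
    end: int
    kind: str  # nucleosome | linker | nfr | tf

    def __post_init__(self) -> None:
        if self.kind not in ACCESSIBLE_KINDS | PROTECTED_KINDS:
            raise ValueError(f"unknown interval kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")


@dataclass
class StateSpec:
    """One latent accessibility state: a mixing weight and a locus tiling."""

    state_id: int
    weight: float
    intervals: list[Interval]

    def accessibility(self, length: int) -> np.ndarray:
        """Boolean accessible/protected track over [0, length)."""
        track = np.zeros(length, dtype=bool)
        prev_end = 0
        for iv in self.intervals:
            if iv.start != prev_end:
                raise ValueError(
                    f"state {self.state_id}: intervals must tile without gaps "
                    f"(gap/overlap at {iv.start})"
                )
            prev_end = iv.end
            track[iv.start : min(iv.end, length)] = iv.kind in ACCESSIBLE_KINDS
        if prev_end < length:
            raise ValueError(
                f"state {self.state_id}: intervals end at {prev_end} < {length}"
            )
        return track


@dataclass
class SimConfig:
    locus_length: int = 50_000
    mean_gpc_spacing: int = 20
    median_read_length: int = 8_000
    read_length_sigma: float = 0.6  # log-normal shape
    coverage: float = 60.0  # molecules per position on average
    p_fail_meth: float = 0.10  # accessible site called unmethylated
    p_spurious_meth: float = 0.05  # protected site called methylated
    p_call_drop: float = 0.05
    n_long_reads: int = 2
    #: override (p_fail_meth, p_spurious_meth) for long reads only
    long_read_noise: tuple[float, float] | None = None
    #: make every fragment span the whole locus (no partial bin coverage)
    full_length_fragments: bool = False
    contig: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_fail_meth", "p_spurious_meth", "p_call_drop"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.long_read_noise is not None:
            for p in self.long_read_noise:
                if not 0.0 <= p <= 1.0:
                    raise ValueError("long_read_noise probabilities must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.locus_length < 2 * self.mean_gpc_spacing:
            raise ValueError("locus too short for the GpC spacing model")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["long_read_noise"] is not None:
            d["long_read_noise"] = list(d["long_read_noise"])
        return d


@dataclass
class SyntheticTruth:
    read_states: dict[str, int]
    site_positions: np.ndarray
    #: (n_states, n_sites) boolean accessibility of every site per state
    site_accessibility: np.ndarray
    states: list[StateSpec]
    config: SimConfig = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": list(self.read_states),
                "state_id": list(self.read_states.values()),
            }
        ).sort_values("read_id", kind="mergesort").reset_index(drop=True)


def make_state(
    state_id: int,
    weight: float,
    locus_length: int,
    rng: np.random.Generator,
    nfr_every: tuple[int, int] = (4, 9),
    linker_range: tuple[int, int] = (20, 80),
    nfr_range: tuple[int, int] = (150, 400),
    tf_range: tuple[int, int] = (35, 50),
    p_tf: float = 0.5,
) -> StateSpec:
    """Build one random state layout: nucleosome arrays punctuated by NFRs.

    After every ``nfr_every``~U draw of nucleosomes an NFR is inserted; with
    probability ``p_tf`` a TF footprint splits it. All draws come from
    ``rng`` so layouts are reproducible.
    """
    intervals: list[Interval] = []
    pos = 0
    until_nfr = int(rng.integers(*nfr_every))

    def push(kind: str, width: int) -> None:
        nonlocal pos
        end = min(pos + width, locus_length)
        if end > pos:
            intervals.append(Interval(pos, end, kind))
            pos = end

    while pos < locus_length:
        if until_nfr == 0:
            width = int(rng.integers(nfr_range[0], nfr_range[1] + 1))
            if rng.random() < p_tf and width >= tf_range[1] + 60:
                tf = int(rng.integers(tf_range[0], tf_range[1] + 1))
                left = (width - tf) // 2
                push("nfr", left)
                push("tf", tf)
                push("nfr", width - tf - left)
            else:
                push("nfr", width)
            until_nfr = int(rng.integers(*nfr_every))
            continue
        push("nucleosome", NUCLEOSOME_BP)
        push("linker", int(rng.integers(linker_range[0], linker_range[1] + 1)))
        until_nfr -= 1
    return StateSpec(state_id=state_id, weight=weight, intervals=intervals)


def default_states(
    n_states: int,
    locus_length: int,
    seed: int,
    weights: list[float] | None = None,
) -> list[StateSpec]:
    """``n_states`` layouts with independent footprint geometry."""
    if weights is None:
        weights = [1.0 / n_states] * n_states
    if len(weights) != n_states or abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must have length n_states and sum to 1")
    rng = np.random.default_rng(seed)
    return [
        make_state(k, weights[k], locus_length, rng) for k in range(n_states)
    ]


def _place_sites(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo = max(2, cfg.mean_gpc_spacing // 2)
    hi = cfg.mean_gpc_spacing + cfg.mean_gpc_spacing // 2
    n_guess = int(2 * cfg.locus_length / lo) + 2
    gaps = rng.integers(lo, hi + 1, size=n_guess)
    pos = np.cumsum(gaps)
    return pos[pos < cfg.locus_length]


def _emit_calls(
    rng: np.random.Generator,
    accessible: np.ndarray,
    p_fail: float,
    p_spurious: float,
    p_drop: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(keep mask, calls 0/1) for one molecule's covered sites."""
    n = len(accessible)
    calls = accessible.astype(np.int8)
    flip = rng.random(n)
    calls[accessible & (flip < p_fail)] = 0
    calls[~accessible & (flip < p_spurious)] = 1
    keep = rng.random(n) >= p_drop
    return keep, calls


def simulate_locus(
    config: SimConfig,
    states: list[StateSpec] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a call table plus its ground truth, fully seeded.

    The number of fragment molecules is coverage * locus_length divided by
    the mean read length; long reads span the whole locus. Returns the
    canonical call table (read_id, contig, position, strand, call 0/1,
    confidence) sorted by (read_id, position).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if states is None:
        states = default_states(3, config.locus_length, seed=config.seed + 1)
    weights = np.array([s.weight for s in states])
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("state weights must sum to 1")

    sites = _place_sites(config, rng)
    acc = np.vstack(
        [s.accessibility(config.locus_length)[sites] for s in states]
    )

    mu = np.log(config.median_read_length)
    mean_len = float(np.exp(mu + config.read_length_sigma**2 / 2))
    n_mols = max(1, round(config.coverage * config.locus_length / mean_len))

    frames: list[pd.DataFrame] = []
    read_states: dict[str, int] = {}

    def emit(read_id: str, start: int, end: int, state: int,
             p_fail: float, p_spurious: float) -> None:
        idx = np.flatnonzero((sites >= start) & (sites < end))
        if idx.size == 0:
            return
        keep, calls = _emit_calls(
            rng, acc[state, idx], p_fail, p_spurious, config.p_call_drop
        )
        if not keep.any():
            return
        read_states[read_id] = state
        frames.append(
            pd.DataFrame(
                {
                    "read_id": read_id,
                    "contig": config.contig,
                    "position": sites[idx[keep]],
                    "strand": "+",
                    "call": calls[keep],
                    "confidence": np.round(rng.uniform(0.85, 1.0, keep.sum()), 4),
                }
            )
        )

    mol_states = rng.choice(len(states), size=n_mols, p=weights)
    if config.full_length_fragments:
        starts = np.zeros(n_mols, dtype=int)
        lengths = np.full(n_mols, config.locus_length)
    else:
        starts = rng.integers(0, config.locus_length, size=n_mols)
        lengths = np.exp(
            rng.normal(mu, config.read_length_sigma, size=n_mols)
        ).astype(int)
    width = len(str(max(n_mols, 1)))
    for i in range(n_mols):
        end = min(config.locus_length, int(starts[i] + lengths[i]))
        emit(
            f"read_{i:0{width}d}",
            int(starts[i]),
            end,
            int(mol_states[i]),
            config.p_fail_meth,
            config.p_spurious_meth,
        )

    long_noise = config.long_read_noise or (
        config.p_fail_meth,
        config.p_spurious_meth,
    )
    long_states = rng.choice(len(states), size=config.n_long_reads, p=weights)
    for i in range(config.n_long_reads):
        emit(
            f"long_{i}",
            0,
            config.locus_length,
            int(long_states[i]),
            long_noise[0],
            long_noise[1],
        )

    if not frames:
        raise ValueError("simulation produced no calls; raise the coverage")
    table = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["read_id", "position"], kind="mergesort")
        .reset_index(drop=True)
    )
    truth = SyntheticTruth(
        read_states=read_states,
        site_positions=sites,
        site_accessibility=acc,
        states=states,
        config=config,
    )
    return table, truth


def score_recovery(
    truth: SyntheticTruth, assignments: pd.DataFrame
) -> dict:
    """Compare phased series labels to the latent states.

    UNASSIGNED / FULLY_* reads are excluded from the ARI and reported.
    The confusion matrix is computed after optimally matching series to
    states with the Hungarian solver; proportion_error is the max absolute
    difference between recovered and true mixing proportions under that
    matching.
    """
    from .stitch import hungarian

    merged = assignments.merge(truth.to_frame(), on="read_id", how="inner")
    numeric = merged[merged["label"].str.fullmatch(r"\d+")]
    excluded = len(merged) - len(numeric)
    if numeric.empty:
        return {
            "ari": float("nan"),
            "n_scored": 0,
            "n_excluded": excluded,
            "confusion": None,
            "proportion_error": float("nan"),
        }
    pred = numeric["label"].astype(int).to_numpy()
    true = numeric["state_id"].to_numpy()
    ari = float(adjusted_rand_score(true, pred))

    n_states = len(truth.states)
    t = max(pred.max() + 1, n_states)
    counts = np.zeros((t, t), dtype=int)
    np.add.at(counts, (pred, np.minimum(true, t - 1)), 1)
    # match series -> states by maximizing agreement
    perm = hungarian(-counts.astype(float))
    confusion = counts[:, :n_states]
    matched = confusion[np.arange(t), np.minimum(perm, n_states - 1)]
    true_props = np.array([s.weight for s in truth.states])
    rec = np.zeros(n_states)
    for series_id in range(t):
        state = perm[series_id]
        if state < n_states:
            rec[state] = (pred == series_id).sum()
    rec = rec / rec.sum() if rec.sum() else rec
    return {
        "ari": ari,
        "n_scored": int(len(numeric)),
        "n_excluded": int(excluded),
        "confusion": confusion,
        "series_to_state": {int(i): int(perm[i]) for i in range(t)},
        "accuracy_matched": float(matched.sum() / len(numeric)),
        "proportion_error": float(np.max(np.abs(rec - true_props))),
        "recovered_proportions": rec,
        "true_proportions": true_props,
    }
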