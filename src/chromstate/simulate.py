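"""Synthetic data from the model's own generative process.

States alternate between closed and open with NB(r, p) sojourns; counts at
each base are geometric draws with the state's emission parameter. The
simulator also synthesizes single-cell-style fragment records (one
fragment per event, the event at the fragment start and a partner end at a
bimodal nucleosome-free / mono-nucleosome insert length away, with cell
barcodes) so that TSV ingestion, pooling and the insert-size QC metric are
all exercisable without real data. Sequence content, GC bias and
mappability are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import defaults
from .durations import NBDurationSpec, sample_durations
from .events import CountTrack, write_events_tsv
from .intervals import GenomicInterval, write_bed_intervals
from .regions import PeakRegion, PeakSet


@dataclass
class FragmentRecord:
    chrom: str
    start: int
    end: int
    barcode: str


@dataclass
class SimulationConfig:
    """Study conditions for the generative simulation.

    Defaults reproduce the model's stated operating point: r = (5, 2)
    substates, per-substate advance probability 1e-4 for both states
    (multi-kilobase sojourns), and emission parameters at the prior means
    (~0.02 events/base closed, ~2 events/base open).
    """

    n_bases: int = 1_000_000
    seed: int = 0
    durations: tuple[NBDurationSpec, NBDurationSpec] = (
        NBDurationSpec(defaults.CLOSED_SUBSTATES, defaults.DEFAULT_DURATION_P),
        NBDurationSpec(defaults.OPEN_SUBSTATES, defaults.DEFAULT_DURATION_P),
    )
    emission_p: tuple[float, float] = (
        defaults.CLOSED_EMISSION_PRIOR[0]
        / (defaults.CLOSED_EMISSION_PRIOR[0] + defaults.CLOSED_EMISSION_PRIOR[1]),
        defaults.OPEN_EMISSION_PRIOR[0]
        / (defaults.OPEN_EMISSION_PRIOR[0] + defaults.OPEN_EMISSION_PRIOR[1]),
    )
    n_cells: int = 0
    chrom: str = "chr1"
    # (mean, sd, weight) per insert-size mode: nucleosome-free and mono-.
    insert_modes: tuple[tuple[float, float, float], ...] = (
        (70.0, 8.0, 0.5),
        (200.0, 12.0, 0.5),
    )

    def __post_init__(self):
        if self.n_bases < 1:
            raise ValueError("n_bases must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    truth_states: np.ndarray
    counts: CountTrack
    truth_regions: PeakSet
    fragments: Optional[list[FragmentRecord]] = None

    @property
    def truth_mask(self) -> np.ndarray:
        return self.truth_states == defaults.OPEN


def _sample_states(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Alternating NB sojourns starting in the closed state."""
    n = config.n_bases
    states = np.empty(n, dtype=np.int8)
    pos = 0
    state = defaults.CLOSED
    # Per-state sojourn buffers, refilled in blocks for speed.
    buffers: list[list[int]] = [[], []]
    while pos < n:
        if not buffers[state]:
            buffers[state] = sample_durations(
                config.durations[state], 1024, rng
            ).tolist()
        d = buffers[state].pop()
        end = min(pos + int(d), n)
        states[pos:end] = state
        pos = end
        state = 1 - state
    return states


def sample_generative(config: SimulationConfig) -> SimulatedDataset:
    """Draw states and counts; reproducible under the config seed."""
    rng = np.random.default_rng(config.seed)
    states = _sample_states(config, rng)
    counts = np.empty(config.n_bases, dtype=np.int64)
    for s, p_g in enumerate(config.emission_p):
        mask = states == s
        counts[mask] = rng.geometric(1.0 - p_g, size=int(mask.sum())) - 1
    track = CountTrack(config.chrom, 0, counts)
    truth_regions = _mask_to_peaks(states == defaults.OPEN, config.chrom)
    fragments = None
    if config.n_cells > 0:
        fragments = _synthesize_fragments(config, counts, rng)
    return SimulatedDataset(config, states, track, truth_regions, fragments)


def _mask_to_peaks(mask: np.ndarray, chrom: str) -> PeakSet:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    regions = [
        PeakRegion(GenomicInterval(chrom, int(s), int(e)), 1.0)
        for s, e in zip(edges[0::2], edges[1::2])
    ]
    return PeakSet(regions)


def _synthesize_fragments(
    config: SimulationConfig, counts: np.ndarray, rng: np.random.Generator
) -> list[FragmentRecord]:
    """One fragment per event: the event at the start, a partner end at a
    bimodal insert length, and a uniformly assigned cell barcode."""
    positions = np.repeat(np.arange(len(counts)), counts)
    n = len(positions)
    modes = config.insert_modes
    weights = np.array([m[2] for m in modes], dtype=float)
    weights /= weights.sum()
    which = rng.choice(len(modes), size=n, p=weights)
    inserts = np.empty(n)
    for i, (mu, sd, _) in enumerate(modes):
        sel = which == i
        inserts[sel] = rng.normal(mu, sd, size=int(sel.sum()))
    inserts = np.maximum(np.round(inserts).astype(np.int64), 20)
    barcodes = rng.integers(config.n_cells, size=n)
    order = rng.permutation(n)
    return [
        FragmentRecord(
            config.chrom,
            int(positions[i]),
            int(positions[i] + inserts[i]),
            f"CELL{barcodes[i]:05d}",
        )
        for i in order
    ]


def emit_fixtures(dataset: SimulatedDataset, directory) -> dict[str, Path]:
    """Write fragments TSV (or events TSV), truth BED and counts bedGraph.

    Reading the TSV back (one event per row start, no offsets) and
    tallying reproduces ``dataset.counts`` exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tsv = directory / "fragments.tsv"
    if dataset.fragments is not None:
        with open(tsv, "w") as fh:
            for frag in dataset.fragments:
                fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\t{frag.barcode}\n")
    else:
        from .events import Tn5Event

        events = [
            Tn5Event(dataset.counts.chrom, int(pos))
            for pos in np.repeat(
                np.arange(len(dataset.counts)), dataset.counts.counts
            )
        ]
        write_events_tsv(events, tsv)
    paths["fragments"] = tsv

    bed = directory / "truth.bed"
    write_bed_intervals(dataset.truth_regions.intervals, bed)
    paths["truth"] = bed

    bedgraph = directory / "counts.bedGraph"
    vals = dataset.counts.counts
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(vals)]])
    with open(bedgraph, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{dataset.counts.chrom}\t{s}\t{e}\t{vals[s]}\n")
    paths["counts"] = bedgraph
    return paths


def downsample_barcodes(
    dataset: SimulatedDataset, fraction: float, seed: int
) -> list[FragmentRecord]:
    """Keep the fragments of a random ``fraction`` of cells."""
    if dataset.fragments is None:
        raise ValueError("dataset has no fragments")
    rng = np.random.default_rng(seed)
    cells = sorted({f.barcode for f in dataset.fragments})
    n_keep = max(1, int(round(fraction * len(cells))))
    keep = set(rng.choice(cells, size=n_keep, replace=False))
    return [f for f in dataset.fragments if f.barcode in keep]
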