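"""Discrete accessible-region calling from posterior tracks, and BED I/O.

Accessible regions are maximal runs of bases whose posterior open
probability meets a fixed threshold chosen a priori (default 0.05; the
region count is insensitive to this value on well-separated posteriors).
Ties at exactly the threshold are included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import defaults
from .events import CountTrack
from .exceptions import ValidationError
from .intervals import GenomicInterval, read_bed  # noqa: F401  (re-exported)
from .posterior import PosteriorTrack


@dataclass(frozen=True)
class PeakRegion:
    interval: GenomicInterval
    mean_p_open: float
    n_events: Optional[int] = None


@dataclass
class PeakSet:
    """Sorted, non-overlapping called regions with per-region summaries."""

    regions: list[PeakRegion]

    def __post_init__(self):
        ivs = [r.interval for r in self.regions]
        if ivs != sorted(ivs):
            raise ValidationError("regions must be sorted")
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValidationError(f"overlapping regions {a} and {b}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [r.interval for r in self.regions]

    @property
    def total_bases(self) -> int:
        return sum(len(r.interval) for r in self.regions)


def call_regions(
    track: PosteriorTrack,
    threshold: float = defaults.DEFAULT_POSTERIOR_THRESHOLD,
    min_length: int = defaults.DEFAULT_MIN_REGION_LENGTH,
    counts: Optional[CountTrack] = None,
    on: str = "open",
) -> PeakSet:
    """Threshold a posterior track into maximal accessible runs.

    ``on="open"`` calls bases with p_open >= threshold (the default);
    ``on="closed"`` instead thresholds the closed-state posterior, calling
    bases with p_closed <= threshold (equivalently p_open >= 1 - threshold).
    Runs shorter than ``min_length`` are discarded.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must lie in (0, 1)")
    if on == "open":
        mask = track.p_open >= threshold
    elif on == "closed":
        mask = (1.0 - track.p_open) <= threshold
    else:
        raise ValueError(f"on must be 'open' or 'closed', got {on!r}")

    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    regions = []
    for s, e in zip(starts, ends):
        if e - s < min_length:
            continue
        iv = GenomicInterval(track.chrom, track.start + int(s), track.start + int(e))
        mean_p = float(track.p_open[s:e].mean())
        n_ev = None
        if counts is not None:
            lo = iv.start - counts.start
            hi = iv.end - counts.start
            if 0 <= lo and hi <= len(counts):
                n_ev = int(counts.counts[lo:hi].sum())
        regions.append(PeakRegion(iv, mean_p, n_ev))
    return PeakSet(regions)


def write_bed(peaks: PeakSet, path) -> None:
    """Write BED4+ lines: chrom, start, end, name, score, mean p_open."""
    with open(path, "w") as fh:
        for i, r in enumerate(peaks):
            score = int(round(1000 * r.mean_p_open))
            n_ev = r.n_events if r.n_events is not None else "."
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\tregion_{i + 1}\t{score}\t.\t{r.mean_p_open:.6g}\t{n_ev}\n"
            )


def count_events_in_regions(
    peaks: PeakSet | Sequence[GenomicInterval], counts: CountTrack
) -> np.ndarray:
    """Total event count inside each region (for replicate correlations)."""
    ivs = peaks.intervals if isinstance(peaks, PeakSet) else list(peaks)
    cum = np.concatenate([[0], np.cumsum(counts.counts)])
    out = np.zeros(len(ivs), dtype=np.int64)
    for i, iv in enumerate(ivs):
        if iv.chrom != counts.chrom:
            continue
        lo = np.clip(iv.start - counts.start, 0, len(counts))
        hi = np.clip(iv.end - counts.start, 0, len(counts))
        out[i] = cum[hi] - cum[lo]
    return out
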