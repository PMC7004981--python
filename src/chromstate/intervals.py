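"""Genomic intervals and BED I/O.

All coordinates are 0-based half-open, matching BED semantics; conversion
to other conventions happens only inside format readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import BedParseError, ValidationError


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < 0:
            raise ValidationError(f"negative coordinate in {self}")
        if self.start >= self.end:
            raise ValidationError(f"empty or inverted interval {self}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or bookended intervals."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


class IntervalIndex:
    """Per-chromosome sorted, merged interval arrays for point/range queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        grouped: dict[str, list[GenomicInterval]] = {}
        for iv in merge_intervals(intervals):
            grouped.setdefault(iv.chrom, []).append(iv)
        self._by_chrom = {
            chrom: (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )
            for chrom, ivs in grouped.items()
        }

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: does each position fall inside any interval (half-open)?"""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._by_chrom:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = self._by_chrom[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        inside = idx >= 0
        inside[inside] = positions[inside] < ends[idx[inside]]
        return inside

    def overlaps_range(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(starts) and starts[i] < end


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ into intervals; extra columns are ignored."""
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError("fewer than 3 columns", lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinate: {exc}", lineno) from exc
            try:
                intervals.append(GenomicInterval(fields[0], start, end))
            except ValidationError as exc:
                raise BedParseError(str(exc), lineno) from exc
    return intervals


def write_bed_intervals(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
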