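"""Tn5 event ingestion, count tracks and inference batches.

The atomic observation is a *Tn5 event*: the corrected genomic coordinate
of one transposase insertion. Events come from aligned-read files (BAM/SAM,
where 5' read starts are offset +4 bp on the plus strand and -5 bp on the
minus strand to land on the center of the Tn5 dimer footprint) or from
fragment/event TSV files as produced by single-cell pipelines. Events are
tallied per base into count tracks, which are the observed vector of the
accessibility model, and split into inference batches at long empty runs.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pysam

from .defaults import ATAC_MINUS_OFFSET, ATAC_PLUS_OFFSET, DEFAULT_MIN_GAP
from .exceptions import InputFormatError, OutOfBoundsError, ValidationError
from .intervals import GenomicInterval, IntervalIndex

logger = logging.getLogger(__name__)

_STRANDS = ("+", "-")


class Tn5Event(NamedTuple):
    """One corrected transposition-event coordinate (0-based)."""

    chrom: str
    pos: int
    strand: str = "+"
    barcode: Optional[str] = None


@dataclass
class CountTrack:
    """Per-base non-negative event counts on a contiguous genomic span."""

    chrom: str
    start: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) < 1:
            raise ValidationError("counts must be a non-empty 1-D array")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.start < 0:
            raise ValidationError("track start must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def end(self) -> int:
        return self.start + len(self.counts)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class Batch:
    """A track slice whose boundaries lie in empty runs or track ends."""

    interval: GenomicInterval
    counts: CountTrack


def read_tn5_events(
    path,
    mode: str = "atac",
    blacklist: Optional[Sequence[GenomicInterval]] = None,
    fragment_ends: str = "start",
) -> list[Tn5Event]:
    """Read Tn5 events from a BAM/SAM file or a (possibly gzipped) TSV.

    Parameters
    ----------
    path
        Source file. ``.bam``/``.sam``/``.cram`` are read as alignments,
        anything else as a tab-separated event/fragment list with columns
        ``chrom start end [barcode] [strand-or-count]``.
    mode
        ``"atac"`` applies the Tn5 center correction (+4 bp to plus-strand
        5' starts, -5 bp to minus-strand 5' starts) when reading
        alignments; ``"dnase"`` applies no shift. TSV rows are taken to
        list already-corrected event coordinates, so the mode only affects
        alignment input.
    blacklist
        Intervals whose events are discarded (half-open containment test).
    fragment_ends
        For TSV input: ``"start"`` yields one event per row at the row's
        start coordinate; ``"both"`` additionally yields the insertion at
        ``end - 1``, matching fragment files in which both fragment ends
        are Tn5 insertions.
    """
    if mode not in ("atac", "dnase"):
        raise ValueError(f"unknown mode {mode!r}")
    if fragment_ends not in ("start", "both"):
        raise ValueError(f"fragment_ends must be 'start' or 'both', got {fragment_ends!r}")
    path = str(path)
    if path.endswith((".bam", ".sam", ".cram")):
        events = _read_alignment_events(path, mode)
    else:
        events = _read_tsv_events(path, fragment_ends)
    if blacklist:
        events = filter_blacklisted(events, blacklist)
    return events


def _read_alignment_events(path: str, mode: str) -> list[Tn5Event]:
    plus_shift = ATAC_PLUS_OFFSET if mode == "atac" else 0
    minus_shift = ATAC_MINUS_OFFSET if mode == "atac" else 0
    events: list[Tn5Event] = []
    n_read = n_skipped = 0
    try:
        af = pysam.AlignmentFile(path, check_sq=False)
    except (OSError, ValueError) as exc:
        raise InputFormatError(f"cannot read alignment file {path}: {exc}") from exc
    with af:
        for read in af.fetch(until_eof=True):
            n_read += 1
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.reference_start is None
                or read.reference_end is None
                or read.reference_end <= read.reference_start
            ):
                n_skipped += 1
                continue
            barcode = read.get_tag("CB") if read.has_tag("CB") else None
            if read.is_reverse:
                # 5' end of a minus-strand read is its highest aligned base.
                pos = read.reference_end - 1 + minus_shift
                strand = "-"
            else:
                pos = read.reference_start + plus_shift
                strand = "+"
            if pos < 0:
                n_skipped += 1
                continue
            events.append(Tn5Event(read.reference_name, pos, strand, barcode))
    logger.info(
        "%s: %d records read, %d events kept, %d skipped",
        path, n_read, len(events), n_skipped,
    )
    return events


def _read_tsv_events(path: str, fragment_ends: str) -> list[Tn5Event]:
    opener = gzip.open if path.endswith(".gz") else open
    events: list[Tn5Event] = []
    n_bad_strand = 0
    try:
        fh = opener(path, "rt")
    except OSError as exc:
        raise InputFormatError(f"cannot read TSV {path}: {exc}") from exc
    with fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or end <= start:
                raise InputFormatError(
                    f"{path}: line {lineno}: invalid span [{start}, {end})"
                )
            barcode = None
            strand = "+"
            count = 1
            for extra in fields[3:]:
                if extra in _STRANDS:
                    strand = extra
                elif extra.isdigit():
                    count = int(extra)
                elif extra in ("*", "."):
                    continue
                elif len(extra) == 1 and not extra.isalnum():
                    n_bad_strand += 1
                else:
                    barcode = extra or None
            for _ in range(count):
                events.append(Tn5Event(chrom, start, strand, barcode))
                if fragment_ends == "both" and end - 1 != start:
                    events.append(Tn5Event(chrom, end - 1, "-", barcode))
    if n_bad_strand:
        logger.warning("%s: %d records with unknown strand symbol", path, n_bad_strand)
    logger.info("%s: %d events read", path, len(events))
    return events


def filter_blacklisted(
    events: Iterable[Tn5Event], blacklist: Sequence[GenomicInterval]
) -> list[Tn5Event]:
    """Drop events whose position lies inside any blacklist interval."""
    events = list(events)
    if not events or not blacklist:
        return events
    index = IntervalIndex(blacklist)
    by_chrom: dict[str, list[int]] = {}
    for i, ev in enumerate(events):
        by_chrom.setdefault(ev.chrom, []).append(i)
    keep = np.ones(len(events), dtype=bool)
    for chrom, idxs in by_chrom.items():
        pos = np.array([events[i].pos for i in idxs], dtype=np.int64)
        inside = index.contains_points(chrom, pos)
        keep[np.array(idxs)[inside]] = False
    kept = [ev for ev, k in zip(events, keep) if k]
    n_removed = len(events) - len(kept)
    if n_removed:
        logger.info("blacklist filtering removed %d of %d events", n_removed, len(events))
    return kept


def write_events_tsv(events: Iterable[Tn5Event], path) -> None:
    """Write one event per row: chrom, start, start+1, barcode, strand."""
    with open(path, "w") as fh:
        for ev in events:
            bc = ev.barcode if ev.barcode is not None else "."
            fh.write(f"{ev.chrom}\t{ev.pos}\t{ev.pos + 1}\t{bc}\t{ev.strand}\n")


def build_count_track(
    events: Iterable[Tn5Event], chrom: str, length: int, start: int = 0
) -> CountTrack:
    """Tally events on ``chrom`` into a per-base count track.

    Barcodes are ignored: single-cell events are pooled base-by-base.
    """
    if length < 1:
        raise ValidationError("length must be >= 1")
    counts = np.zeros(length, dtype=np.int64)
    for ev in events:
        if ev.chrom != chrom:
            raise OutOfBoundsError(f"event {ev} not on {chrom}")
        rel = ev.pos - start
        if rel < 0 or rel >= length:
            raise OutOfBoundsError(
                f"event {ev} outside [{start}, {start + length}) on {chrom}"
            )
        counts[rel] += 1
    return CountTrack(chrom, start, counts)


def segment_batches(track: CountTrack, min_gap: int = DEFAULT_MIN_GAP) -> list[Batch]:
    """Split a track into batches separated by zero runs of >= ``min_gap``.

    The concatenation of the returned batches plus the removed zero gaps
    reconstructs the track exactly; every nonzero base lies in a batch.
    An all-zero track yields no batches.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    counts = track.counts
    nonzero = np.flatnonzero(counts)
    if len(nonzero) == 0:
        return []
    batches: list[Batch] = []
    # Candidate cut points: gaps between consecutive nonzero bases, plus the
    # leading/trailing zero runs.
    seg_start = 0 if nonzero[0] < min_gap else int(nonzero[0])
    prev = nonzero[0]
    for nz in nonzero[1:]:
        if nz - prev - 1 >= min_gap:
            batches.append(_make_batch(track, seg_start, int(prev) + 1))
            seg_start = int(nz)
        prev = nz
    tail_zeros = len(counts) - 1 - int(nonzero[-1])
    seg_end = int(nonzero[-1]) + 1 if tail_zeros >= min_gap else len(counts)
    batches.append(_make_batch(track, seg_start, seg_end))
    return batches


def _make_batch(track: CountTrack, lo: int, hi: int) -> Batch:
    sub = CountTrack(track.chrom, track.start + lo, track.counts[lo:hi].copy())
    return Batch(interval=sub.interval, counts=sub)
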