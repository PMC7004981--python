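"""Data-set quality metrics.

Scalar library-quality summaries computed on one chromosome (chromosome 1
by convention): fraction of properly paired reads inside called peaks
(FRIP), promoter signal-to-noise ratio, the mono-nucleosome to
nucleosome-free insert-size ratio, an extrapolated genome-wide read count,
and the dynamic range of the count track in bits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pysam

from . import defaults
from .events import CountTrack
from .exceptions import UndefinedMetricError
from .intervals import GenomicInterval, IntervalIndex


@dataclass
class QCReport:
    frip: Optional[float] = None
    snr: Optional[float] = None
    snr_capped: bool = False
    insert_ratio: Optional[float] = None
    extrapolated_reads: Optional[int] = None
    dynamic_range_bits: Optional[float] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key}\t{value}\n")


def _proper_pairs(source, chrom: str):
    """Yield (start, end, isize) of properly paired, mated reads on chrom."""
    af = source if isinstance(source, pysam.AlignmentFile) else pysam.AlignmentFile(
        str(source), check_sq=False
    )
    close = not isinstance(source, pysam.AlignmentFile)
    try:
        for read in af.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_proper_pair
                or read.mate_is_unmapped
                or read.reference_name != chrom
            ):
                continue
            yield read.reference_start, read.reference_end, read.template_length
    finally:
        if close:
            af.close()


def compute_frip(
    reads: Union[str, pysam.AlignmentFile, Sequence[tuple[int, int]]],
    peaks: Sequence[GenomicInterval],
    chrom: str = "chr1",
) -> float:
    """Fraction of properly paired reads overlapping any peak on ``chrom``.

    ``reads`` may be a BAM/SAM path, an open alignment file, or an already
    extracted sequence of (start, end) read spans on ``chrom``.
    """
    if isinstance(reads, (str,)) or isinstance(reads, pysam.AlignmentFile):
        spans = [(s, e) for s, e, _ in _proper_pairs(reads, chrom)]
    else:
        spans = [(s, e) for s, e in reads]
    if not spans:
        raise UndefinedMetricError(f"no qualifying reads on {chrom}")
    peak_ivs = [iv for iv in peaks if iv.chrom == chrom]
    if not peak_ivs:
        return 0.0
    index = IntervalIndex(peak_ivs)
    n_in = sum(1 for s, e in spans if index.overlaps_range(chrom, s, e))
    return n_in / len(spans)


def compute_snr(
    coverage: Union[CountTrack, np.ndarray],
    gene_starts: Sequence[tuple[int, str]],
    upstream: int = defaults.PROMOTER_UPSTREAM,
    downstream: int = defaults.PROMOTER_DOWNSTREAM,
) -> tuple[float, bool]:
    """Promoter signal-to-noise: mean coverage inside strand-aware promoter
    windows over mean coverage outside.

    Promoters span ``upstream`` bases against and ``downstream`` bases along
    gene orientation from each gene start. Returns ``(snr, capped)``;
    ``capped`` flags a zero background with nonzero promoter signal, where
    the ratio diverges and infinity is reported.
    """
    cov = coverage.counts if isinstance(coverage, CountTrack) else np.asarray(coverage)
    offset = coverage.start if isinstance(coverage, CountTrack) else 0
    if len(gene_starts) < 1:
        raise UndefinedMetricError("no gene starts supplied")
    mask = np.zeros(len(cov), dtype=bool)
    for pos, strand in gene_starts:
        if strand == "-":
            lo, hi = pos - downstream, pos + upstream
        else:
            lo, hi = pos - upstream, pos + downstream
        lo = max(lo - offset, 0)
        hi = min(hi - offset, len(cov))
        if lo < hi:
            mask[lo:hi] = True
    if not mask.any() or mask.all():
        raise UndefinedMetricError("promoter windows cover none or all of the track")
    signal = float(cov[mask].mean())
    background = float(cov[~mask].mean())
    if background == 0.0:
        if signal == 0.0:
            raise UndefinedMetricError("zero coverage inside and outside promoters")
        warnings.warn("zero background coverage; SNR capped at infinity")
        return float("inf"), True
    return signal / background, False


def insert_size_metric(
    read_pairs: Union[str, pysam.AlignmentFile, Iterable[int]],
    chrom: str = "chr1",
    mono_window: tuple[int, int] = (190, 210),
    free_window: tuple[int, int] = (60, 80),
) -> float:
    """Mono-nucleosome (190-210 bp) to nucleosome-free (60-80 bp) insert ratio.

    ``read_pairs`` may be an alignment source (template lengths of properly
    paired reads on ``chrom`` are used) or an iterable of insert sizes.
    Window bounds are inclusive.
    """
    if isinstance(read_pairs, (str, pysam.AlignmentFile)):
        isizes = [abs(i) for _, _, i in _proper_pairs(read_pairs, chrom) if i > 0]
    else:
        isizes = [abs(int(i)) for i in read_pairs]
    isizes = np.asarray(isizes)
    n_mono = int(((isizes >= mono_window[0]) & (isizes <= mono_window[1])).sum())
    n_free = int(((isizes >= free_window[0]) & (isizes <= free_window[1])).sum())
    if n_free == 0:
        raise UndefinedMetricError("no read pairs in the nucleosome-free window")
    return n_mono / n_free


def insert_size_histogram(
    read_pairs: Union[str, pysam.AlignmentFile, Iterable[int]],
    chrom: str = "chr1",
    max_insert: int = 1000,
) -> np.ndarray:
    """Histogram of absolute insert sizes, one bin per bp up to ``max_insert``."""
    if isinstance(read_pairs, (str, pysam.AlignmentFile)):
        isizes = [abs(i) for _, _, i in _proper_pairs(read_pairs, chrom) if i > 0]
    else:
        isizes = [abs(int(i)) for i in read_pairs]
    return np.bincount(
        np.clip(np.asarray(isizes, dtype=np.int64), 0, max_insert), minlength=max_insert + 1
    )


def extrapolate_reads(count_chr1: int, len_chr1: int, genome_length: int) -> int:
    """Genome-wide read count extrapolated from chromosome 1."""
    if len_chr1 <= 0 or genome_length <= 0:
        raise ValueError("lengths must be positive")
    return int(round(count_chr1 * genome_length / len_chr1))


def dynamic_range_bits(track: Union[CountTrack, np.ndarray]) -> float:
    """log2 of the max/min nonzero per-base count (dynamic range in bits)."""
    counts = track.counts if isinstance(track, CountTrack) else np.asarray(track)
    nonzero = counts[counts > 0]
    if len(nonzero) == 0:
        raise UndefinedMetricError("all-zero track has no dynamic range")
    return float(np.log2(nonzero.max() / nonzero.min()))
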