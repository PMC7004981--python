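"""Validation metrics against curated regions and ChIP-seq summits.

Reference-region metrics: fraction of reference peaks covered by at least
one called base (fpc), the per-peak covered fraction averaged over peaks
(apc, mean +/- s.e.m.), and the pooled covered-base fraction (tc, the
length-weighted mean of the per-peak fractions). Summit metrics: precision
(called peaks containing >= 1 summit), recall (summits covered, reported
both as a raw count and as a fraction), and their harmonic-mean F1. All
overlaps are half-open: a summit at a peak's end coordinate is outside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import UndefinedMetricError
from .intervals import GenomicInterval, IntervalIndex, merge_intervals


def _covered_bases(peak: GenomicInterval, merged: Sequence[GenomicInterval]) -> int:
    total = 0
    for iv in merged:
        if iv.chrom != peak.chrom:
            continue
        lo = max(iv.start, peak.start)
        hi = min(iv.end, peak.end)
        if lo < hi:
            total += hi - lo
    return total


def per_peak_coverage(
    reference: Sequence[GenomicInterval], called: Sequence[GenomicInterval]
) -> np.ndarray:
    """Covered fraction pc of each reference peak."""
    if not reference:
        raise UndefinedMetricError("empty reference peak set")
    merged = merge_intervals(called)
    return np.array([_covered_bases(p, merged) / len(p) for p in reference])


def fraction_peaks_covered(
    reference: Sequence[GenomicInterval], called: Sequence[GenomicInterval]
) -> float:
    """Fraction of reference peaks intersected by at least one called base."""
    pc = per_peak_coverage(reference, called)
    return float((pc > 0).mean())


def average_peak_coverage(
    reference: Sequence[GenomicInterval], called: Sequence[GenomicInterval]
) -> tuple[float, float]:
    """Mean and standard error of the per-peak covered fraction."""
    pc = per_peak_coverage(reference, called)
    sem = float(pc.std(ddof=1) / np.sqrt(len(pc))) if len(pc) > 1 else 0.0
    return float(pc.mean()), sem


def total_coverage(
    reference: Sequence[GenomicInterval], called: Sequence[GenomicInterval]
) -> float:
    """Intersected bases over total reference bases (length-weighted pc mean)."""
    if not reference:
        raise UndefinedMetricError("empty reference peak set")
    merged = merge_intervals(called)
    lengths = np.array([len(p) for p in reference])
    covered = np.array([_covered_bases(p, merged) for p in reference])
    return float(covered.sum() / lengths.sum())


@dataclass
class PrecisionRecall:
    precision: float
    recall_count: int
    recall_fraction: float
    f1: float


def precision_recall_f1(
    called: Sequence[GenomicInterval],
    chip_summits: Sequence[tuple[str, int]],
) -> PrecisionRecall:
    """Summit-based precision/recall.

    Precision: fraction of called peaks containing at least one summit.
    Recall: summits falling inside any peak, reported as the raw count and
    as a fraction of all summits; F1 is the harmonic mean of precision and
    the recall fraction.
    """
    if not called:
        raise UndefinedMetricError("empty called peak set")
    index = IntervalIndex(called)
    covered = np.zeros(len(chip_summits), dtype=bool)
    for i, (chrom, pos) in enumerate(chip_summits):
        covered[i] = bool(index.contains_points(chrom, np.array([pos]))[0])
    n_with_summit = sum(
        1
        for iv in called
        if any(iv.contains(chrom, pos) for chrom, pos in chip_summits)
    )
    precision = n_with_summit / len(called)
    recall_count = int(covered.sum())
    recall_fraction = float(covered.mean()) if len(chip_summits) else 0.0
    if precision + recall_fraction > 0:
        f1 = 2 * precision * recall_fraction / (precision + recall_fraction)
    else:
        f1 = 0.0
    return PrecisionRecall(precision, recall_count, recall_fraction, f1)


def region_f1(
    truth: Sequence[GenomicInterval], called: Sequence[GenomicInterval]
) -> float:
    """Region-level F1: recall = fpc(truth, called), precision = fpc(called, truth)."""
    if not truth or not called:
        return 0.0
    recall = fraction_peaks_covered(truth, called)
    precision = fraction_peaks_covered(called, truth)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def base_level_f1(truth_mask: np.ndarray, called_mask: np.ndarray) -> float:
    """Per-base F1 of a called open mask against the true open mask."""
    truth_mask = np.asarray(truth_mask, dtype=bool)
    called_mask = np.asarray(called_mask, dtype=bool)
    tp = int((truth_mask & called_mask).sum())
    fp = int((~truth_mask & called_mask).sum())
    fn = int((truth_mask & ~called_mask).sum())
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


@dataclass
class BenchmarkResult:
    fpc: float
    apc_mean: float
    apc_sem: float
    tc: float
    precision: Optional[float] = None
    recall_count: Optional[int] = None
    recall_fraction: Optional[float] = None
    f1: Optional[float] = None
    n_reference: int = 0


def benchmark_annotations(
    reference: Sequence[GenomicInterval],
    called: Sequence[GenomicInterval],
    chip_summits: Optional[Sequence[tuple[str, int]]] = None,
) -> BenchmarkResult:
    """All reference-region metrics, plus summit metrics when given."""
    apc_mean, apc_sem = average_peak_coverage(reference, called)
    result = BenchmarkResult(
        fpc=fraction_peaks_covered(reference, called),
        apc_mean=apc_mean,
        apc_sem=apc_sem,
        tc=total_coverage(reference, called),
        n_reference=len(reference),
    )
    if chip_summits is not None and called:
        pr = precision_recall_f1(called, chip_summits)
        result.precision = pr.precision
        result.recall_count = pr.recall_count
        result.recall_fraction = pr.recall_fraction
        result.f1 = pr.f1
    return result
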