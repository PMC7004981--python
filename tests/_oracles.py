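"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive enumeration, per-element
scans) and shares no code path with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_marginals(logpots: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Exact posterior marginals by summing over all substate sequences.

    Returns (marginals (B, K), log_evidence). Exponential in B; only for
    tiny problems.
    """
    B, K = logpots.shape
    log_A = np.where(A > 0, np.log(np.where(A > 0, A, 1.0)), -np.inf)
    log_pi = np.where(pi > 0, np.log(np.where(pi > 0, pi, 1.0)), -np.inf)
    weights = np.zeros((B, K))
    total = 0.0
    log_terms = []
    seqs = []
    for seq in itertools.product(range(K), repeat=B):
        lp = log_pi[seq[0]] + logpots[0, seq[0]]
        for b in range(1, B):
            lp += log_A[seq[b - 1], seq[b]] + logpots[b, seq[b]]
        log_terms.append(lp)
        seqs.append(seq)
    log_terms = np.array(log_terms)
    m = log_terms.max()
    probs = np.exp(log_terms - m)
    Z = probs.sum()
    for seq, p in zip(seqs, probs):
        for b, k in enumerate(seq):
            weights[b, k] += p
    return weights / Z, float(np.log(Z) + m)


def brute_blacklist_mask(events, intervals):
    """Per-event flag: does the event fall in any interval (half-open)?"""
    out = []
    for ev in events:
        hit = any(
            iv.chrom == ev.chrom and iv.start <= ev.pos < iv.end for iv in intervals
        )
        out.append(hit)
    return out


def brute_fpc(reference, called):
    n = 0
    for ref in reference:
        if any(
            c.chrom == ref.chrom and c.start < ref.end and ref.start < c.end
            for c in called
        ):
            n += 1
    return n / len(reference)


def brute_per_peak_coverage(reference, called):
    out = []
    for ref in reference:
        covered = set()
        for c in called:
            if c.chrom != ref.chrom:
                continue
            for b in range(max(ref.start, c.start), min(ref.end, c.end)):
                covered.add(b)
        out.append(len(covered) / (ref.end - ref.start))
    return np.array(out)


def brute_tc(reference, called):
    inter = 0
    total = 0
    for ref in reference:
        total += ref.end - ref.start
        covered = set()
        for c in called:
            if c.chrom != ref.chrom:
                continue
            covered.update(range(max(ref.start, c.start), min(ref.end, c.end)))
        inter += len(covered)
    return inter / total


def brute_precision_recall(called, summits):
    n_peaks_hit = sum(
        1
        for c in called
        if any(s[0] == c.chrom and c.start <= s[1] < c.end for s in summits)
    )
    n_summits_hit = sum(
        1
        for s in summits
        if any(c.chrom == s[0] and c.start <= s[1] < c.end for c in called)
    )
    precision = n_peaks_hit / len(called)
    recall = n_summits_hit / len(summits)
    return precision, n_summits_hit, recall


def brute_frip(spans, peaks):
    n_in = 0
    for s, e in spans:
        if any(p.start < e and s < p.end for p in peaks):
            n_in += 1
    return n_in / len(spans)
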