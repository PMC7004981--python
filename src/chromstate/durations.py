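"""Negative-binomial state-duration law.

A macro-state sojourn d >= 1 follows

    P(d = l + 1 | r, p) = C(l + r - 1, l) p^r (1 - p)^l,

equivalently d = 1 + sum_{i=1..r} z_i with z_i shifted-geometric: each z_i
counts extra dwell bases accrued with probability (1 - p) each, so p is the
per-substate advance probability and the mean sojourn is 1 + r (1 - p) / p.
This is exactly the scipy ``nbinom(r, p)`` law on l = d - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError


@dataclass(frozen=True)
class NBDurationSpec:
    """Number of geometric summands ``r`` and advance probability ``p``."""

    r: int
    p: float

    def __post_init__(self):
        if not (isinstance(self.r, (int, np.integer)) and self.r >= 1):
            raise ValidationError(f"r must be an integer >= 1, got {self.r!r}")
        if not (0.0 < self.p < 1.0):
            raise ValidationError(f"p must lie in (0, 1), got {self.p!r}")

    @property
    def mean(self) -> float:
        return 1.0 + self.r * (1.0 - self.p) / self.p


def nb_duration_pmf(d, spec: NBDurationSpec):
    """Probability of a sojourn of exactly ``d`` bases (d >= 1)."""
    d_arr = np.asarray(d)
    if (d_arr < 1).any():
        raise ValidationError("duration must be >= 1")
    out = stats.nbinom.pmf(d_arr - 1, spec.r, spec.p)
    return float(out) if np.isscalar(d) else out


def sample_durations(spec: NBDurationSpec, size: int, rng: np.random.Generator):
    """Draw sojourn lengths d = 1 + NB(r, p)."""
    return 1 + rng.negative_binomial(spec.r, spec.p, size=size)


def entry_weights(spec: NBDurationSpec) -> np.ndarray:
    """Binomial entry distribution over the r duration substates.

    Entering substate j (0-based, traversal j -> r-1) has weight
    Binom(j; r - 1, p): the number of substates skipped on entry is
    Binomial(r - 1, p), which makes the substate chain's sojourn law equal
    the NB duration law exactly.
    """
    j = np.arange(spec.r)
    return stats.binom.pmf(j, spec.r - 1, spec.p)
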