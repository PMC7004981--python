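"""Geometric count emissions with conjugate Beta priors.

Counts at a base in macro-state i follow p(x | p_i) = p_i^x (1 - p_i),
x = 0, 1, 2, ...; the mean is p_i / (1 - p_i). The Beta(a0, b0) prior on
p_i is conjugate: observing counts x_b with responsibilities g_b updates
(a, b) -> (a0 + sum g_b x_b, b0 + sum g_b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma

from .exceptions import ValidationError


@dataclass(frozen=True)
class GeometricEmission:
    p_g: float
    prior_a: float = 1.0
    prior_b: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.p_g < 1.0):
            raise ValidationError(f"p_g must lie in (0, 1), got {self.p_g!r}")
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValidationError("pseudocounts must be positive")

    @property
    def mean_count(self) -> float:
        return self.p_g / (1.0 - self.p_g)


def geometric_emission_logpmf(x, p_g: float):
    """log p(x | p_g) = x log p_g + log(1 - p_g), for integer x >= 0."""
    x_arr = np.asarray(x)
    if (x_arr < 0).any():
        raise ValidationError("counts must be non-negative")
    if not (0.0 < p_g < 1.0):
        raise ValidationError(f"p_g must lie in (0, 1), got {p_g!r}")
    out = x_arr * np.log(p_g) + np.log1p(-p_g)
    return float(out) if np.isscalar(x) else out


def sample_counts(p_g: float, size, rng: np.random.Generator):
    """Draw counts with pmf p_g^x (1 - p_g) (numpy geometric, shifted)."""
    return rng.geometric(1.0 - p_g, size=size) - 1


def expected_log_params(a: float, b: float) -> tuple[float, float]:
    """(E[log p], E[log(1-p)]) under Beta(a, b)."""
    d = digamma(a + b)
    return digamma(a) - d, digamma(b) - d
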