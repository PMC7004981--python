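"""Scaled forward-backward recursion for the embedded chain.

The recursion runs in linear space with per-base scaling constants, which
keeps it stable on chromosome-length tracks; per-base potentials are
shifted by their row maximum in log space first, so arbitrarily unlikely
counts cannot underflow. The numba kernel is the hot path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .embedding import EmbeddedHMM
from .events import CountTrack
from .exceptions import NumericalError


@njit(cache=True)
def _fb_kernel(P, A, pi):
    """Scaled forward-backward. P holds per-base potentials (linear space).

    Returns (gamma, log_c, fail_index); fail_index >= 0 flags the first
    base whose scaling constant vanished or went non-finite.
    """
    B, K = P.shape
    gamma = np.empty((B, K))
    log_c = np.empty(B)

    # Forward pass; gamma temporarily holds scaled alpha.
    c = 0.0
    for k in range(K):
        v = pi[k] * P[0, k]
        gamma[0, k] = v
        c += v
    if not (c > 0.0 and np.isfinite(c)):
        return gamma, log_c, 0
    for k in range(K):
        gamma[0, k] /= c
    log_c[0] = np.log(c)

    for b in range(1, B):
        c = 0.0
        for j in range(K):
            s = 0.0
            for i in range(K):
                s += gamma[b - 1, i] * A[i, j]
            v = s * P[b, j]
            gamma[b, j] = v
            c += v
        if not (c > 0.0 and np.isfinite(c)):
            return gamma, log_c, b
        for j in range(K):
            gamma[b, j] /= c
        log_c[b] = np.log(c)

    # Backward pass with a running beta vector; gamma becomes alpha * beta.
    beta = np.ones(K)
    tmp = np.empty(K)
    for b in range(B - 2, -1, -1):
        for j in range(K):
            tmp[j] = P[b + 1, j] * beta[j]
        for i in range(K):
            s = 0.0
            for j in range(K):
                s += A[i, j] * tmp[j]
            beta[i] = s / np.exp(log_c[b + 1])
        tot = 0.0
        for k in range(K):
            gamma[b, k] *= beta[k]
            tot += gamma[b, k]
        for k in range(K):
            gamma[b, k] /= tot

    return gamma, log_c, -1


@dataclass
class FBResult:
    """Per-base substate marginals, macro marginals and log-evidence."""

    gamma: np.ndarray
    log_evidence: float
    p_macro: np.ndarray

    @property
    def p_open(self) -> np.ndarray:
        return self.p_macro[:, 1]


def emission_logpots(
    counts: np.ndarray, substate_macro: np.ndarray, log_p: np.ndarray, log_1mp: np.ndarray
) -> np.ndarray:
    """Per-base, per-substate geometric log-potentials.

    ``log_p``/``log_1mp`` are per macro-state (point values or variational
    expected logs).
    """
    lp = log_p[substate_macro]
    l1 = log_1mp[substate_macro]
    return counts[:, None] * lp[None, :] + l1[None, :]


def run_forward_backward(
    logpots: np.ndarray, A: np.ndarray, pi: np.ndarray
) -> FBResult | tuple[np.ndarray, float]:
    """Forward-backward on arbitrary log-potentials; returns (gamma, logZ)."""
    shift = logpots.max(axis=1)
    P = np.exp(logpots - shift[:, None])
    gamma, log_c, fail = _fb_kernel(P, A, pi)
    if fail >= 0:
        raise NumericalError(f"forward-backward scaling failed at base index {fail}")
    log_z = float(log_c.sum() + shift.sum())
    return gamma, log_z


def forward_backward(model: EmbeddedHMM, counts: CountTrack | np.ndarray) -> FBResult:
    """Substate posteriors and log-evidence under the model's point parameters."""
    x = counts.counts if isinstance(counts, CountTrack) else np.asarray(counts)
    model.validate()
    log_p = np.log([em.p_g for em in model.emissions])
    log_1mp = np.log1p([-em.p_g for em in model.emissions])
    logpots = emission_logpots(x, model.substate_macro, log_p, log_1mp)
    pi = model.initial_substate_distribution()
    gamma, log_z = run_forward_backward(logpots, model.transition, pi)
    return FBResult(gamma, log_z, macro_marginals(model, gamma))


def macro_marginals(model: EmbeddedHMM, gamma: np.ndarray) -> np.ndarray:
    """Aggregate substate marginals to (closed, open) macro marginals."""
    out = np.empty((gamma.shape[0], model.n_macro))
    for m, block in enumerate(model.macro_blocks()):
        out[:, m] = gamma[:, block].sum(axis=1)
    return out
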