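"""Variational Bayesian accessibility model and its results object.

``AccessibilityHSMM`` wraps a per-base Tn5 event count track in the
negative-binomial-duration semi-Markov model: latent chromatin state
(closed/open) with NB(r, p) sojourns, geometric count emissions with
conjugate Beta priors, and a Dirichlet prior on the initial state of each
inference batch. ``fit`` runs mean-field coordinate ascent: forward-
backward under expected-log parameters alternating with conjugate
Beta/Dirichlet pseudocount updates, monitored by an evidence lower bound
(ELBO) that is non-decreasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import digamma, gammaln

from . import defaults
from .durations import NBDurationSpec
from .embedding import EmbeddedHMM, build_embedding
from .emissions import GeometricEmission
from .events import Batch, CountTrack, build_count_track, read_tn5_events, segment_batches
from .inference import emission_logpots, macro_marginals, run_forward_backward
from .posterior import PosteriorTrack, write_bedgraph
from .regions import PeakSet, call_regions


class ConvergenceWarning(UserWarning):
    pass


def _kl_beta(a, b, a0, b0) -> float:
    """KL(Beta(a, b) || Beta(a0, b0))."""
    return float(
        gammaln(a + b) - gammaln(a) - gammaln(b)
        - (gammaln(a0 + b0) - gammaln(a0) - gammaln(b0))
        + (a - a0) * digamma(a)
        + (b - b0) * digamma(b)
        - (a + b - a0 - b0) * digamma(a + b)
    )


def _kl_dirichlet(alpha, alpha0) -> float:
    alpha = np.asarray(alpha, dtype=float)
    alpha0 = np.asarray(alpha0, dtype=float)
    s, s0 = alpha.sum(), alpha0.sum()
    return float(
        gammaln(s) - gammaln(alpha).sum()
        - (gammaln(s0) - gammaln(alpha0).sum())
        + ((alpha - alpha0) * (digamma(alpha) - digamma(s))).sum()
    )


@dataclass
class VBState:
    """Variational posterior pseudocounts (Beta per state, Dirichlet init)."""

    emission_a: np.ndarray
    emission_b: np.ndarray
    initial_alpha: np.ndarray

    def expected_logs(self):
        d = digamma(self.emission_a + self.emission_b)
        return digamma(self.emission_a) - d, digamma(self.emission_b) - d

    def expected_log_initial(self):
        return digamma(self.initial_alpha) - digamma(self.initial_alpha.sum())

    @property
    def emission_posterior_mean(self) -> np.ndarray:
        return self.emission_a / (self.emission_a + self.emission_b)


class AccessibilityHSMM:
    """Accessibility model over one contiguous count track.

    Parameters
    ----------
    counts
        Per-base Tn5 event counts (``CountTrack``).
    substates
        NB ``r`` per macro-state (closed, open); the embedded chain has
        ``sum(substates)`` substates.
    duration_p
        Fixed per-substate advance probability per macro-state (the NB
        ``p``); not learned.
    emission_priors
        Beta pseudocounts (a0, b0) per macro-state.
    initial_pseudocounts
        Dirichlet pseudocounts over (closed, open) for batch starts.
    min_gap
        Zero-run length that separates inference batches.
    """

    def __init__(
        self,
        counts: CountTrack,
        *,
        substates: tuple[int, int] = (defaults.CLOSED_SUBSTATES, defaults.OPEN_SUBSTATES),
        duration_p: tuple[float, float] = (defaults.DEFAULT_DURATION_P, defaults.DEFAULT_DURATION_P),
        emission_priors=(defaults.CLOSED_EMISSION_PRIOR, defaults.OPEN_EMISSION_PRIOR),
        initial_pseudocounts=defaults.INITIAL_PSEUDOCOUNTS,
        min_gap: int = defaults.DEFAULT_MIN_GAP,
        macro_transition: Optional[np.ndarray] = None,
    ):
        self.counts = counts
        self.min_gap = min_gap
        durations = (
            NBDurationSpec(substates[0], duration_p[0]),
            NBDurationSpec(substates[1], duration_p[1]),
        )
        emissions = tuple(
            GeometricEmission(a0 / (a0 + b0), a0, b0) for a0, b0 in emission_priors
        )
        self.embedding: EmbeddedHMM = build_embedding(
            durations, macro_transition, emissions, initial_pseudocounts
        )
        self.batches: list[Batch] = segment_batches(counts, min_gap)
        if not self.batches:
            # Nothing but zeros: fit the whole track as one batch so the
            # prior-driven posterior is still computed numerically.
            self.batches = [Batch(counts.interval, counts)]

    @classmethod
    def from_events(cls, events, chrom: str, length: int, **kwargs) -> "AccessibilityHSMM":
        track = build_count_track(events, chrom, length)
        return cls(track, **kwargs)

    @classmethod
    def from_file(
        cls, path, chrom: str, length: int, mode: str = "atac", blacklist=None, **kwargs
    ) -> "AccessibilityHSMM":
        events = read_tn5_events(path, mode=mode, blacklist=blacklist)
        events = [ev for ev in events if ev.chrom == chrom and ev.pos < length]
        return cls.from_events(events, chrom, length, **kwargs)

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        max_iter: int = defaults.DEFAULT_MAX_ITER,
        tol: float = defaults.DEFAULT_TOL,
    ) -> "AccessibilityResults":
        """Mean-field variational fit; returns the results object."""
        emb = self.embedding
        a0 = np.array([em.prior_a for em in emb.emissions])
        b0 = np.array([em.prior_b for em in emb.emissions])
        alpha0 = emb.initial_pseudocounts.copy()
        state = VBState(a0.copy(), b0.copy(), alpha0.copy())

        xs = [batch.counts.counts for batch in self.batches]
        elbo_trace: list[float] = []
        converged = False
        gammas_macro: list[np.ndarray] = []
        log_evidences: list[float] = []

        for _ in range(max_iter):
            log_p, log_1mp = state.expected_logs()
            log_pi_macro = state.expected_log_initial()
            pi_sub = emb.initial_substate_distribution(np.exp(log_pi_macro))

            nx = np.zeros(emb.n_macro)
            n = np.zeros(emb.n_macro)
            init_counts = np.zeros(emb.n_macro)
            log_z_total = 0.0
            gammas_macro = []
            log_evidences = []
            for x in xs:
                logpots = emission_logpots(x, emb.substate_macro, log_p, log_1mp)
                gamma, log_z = run_forward_backward(logpots, emb.transition, pi_sub)
                gm = macro_marginals(emb, gamma)
                gammas_macro.append(gm)
                log_evidences.append(log_z)
                log_z_total += log_z
                nx += gm.T @ x
                n += gm.sum(axis=0)
                init_counts += gm[0]

            kl = (
                _kl_beta(state.emission_a[0], state.emission_b[0], a0[0], b0[0])
                + _kl_beta(state.emission_a[1], state.emission_b[1], a0[1], b0[1])
                + _kl_dirichlet(state.initial_alpha, alpha0)
            )
            elbo = log_z_total - kl
            if elbo_trace:
                prev = elbo_trace[-1]
                if abs(elbo - prev) <= tol * max(1.0, abs(prev)):
                    elbo_trace.append(elbo)
                    converged = True
                    break
            elbo_trace.append(elbo)

            state.emission_a = a0 + nx
            state.emission_b = b0 + n
            state.initial_alpha = alpha0 + init_counts

        if not converged:
            warnings.warn(
                f"variational fit did not converge in {max_iter} iterations",
                ConvergenceWarning,
            )

        p_open_full = np.zeros(len(self.counts))
        for batch, gm in zip(self.batches, gammas_macro):
            lo = batch.interval.start - self.counts.start
            p_open_full[lo : lo + len(batch.counts)] = gm[:, 1]
        np.clip(p_open_full, 0.0, 1.0, out=p_open_full)
        posterior = PosteriorTrack(self.counts.chrom, self.counts.start, p_open_full)

        return AccessibilityResults(
            model=self,
            vb=state,
            elbo_trace=np.asarray(elbo_trace),
            converged=converged,
            posterior=posterior,
            batch_log_evidence=np.asarray(log_evidences),
        )


@dataclass
class AccessibilityResults:
    """Posterior pseudocounts, ELBO trace and per-base posterior state."""

    model: AccessibilityHSMM
    vb: VBState
    elbo_trace: np.ndarray
    converged: bool
    posterior: PosteriorTrack
    batch_log_evidence: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def emission_pseudocounts(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vb.emission_a, self.vb.emission_b

    @property
    def initial_pseudocounts(self) -> np.ndarray:
        return self.vb.initial_alpha

    @property
    def emission_rate(self) -> np.ndarray:
        """Posterior-mean events/base per state: E[p]/(1 - E[p])."""
        p = self.vb.emission_posterior_mean
        return p / (1.0 - p)

    @property
    def n_iter(self) -> int:
        return len(self.elbo_trace)

    def call_regions(
        self,
        threshold: float = defaults.DEFAULT_POSTERIOR_THRESHOLD,
        min_length: int = defaults.DEFAULT_MIN_REGION_LENGTH,
        on: str = "open",
    ) -> PeakSet:
        return call_regions(
            self.posterior, threshold, min_length, counts=self.model.counts, on=on
        )

    def to_bedgraph(self, path) -> None:
        write_bedgraph(self.posterior, path)

    def summary(self) -> str:
        from scipy.stats import beta as beta_dist

        emb = self.model.embedding
        p_mean = self.vb.emission_posterior_mean
        lines = [
            "Accessibility HSMM fit (variational Bayes)",
            "=" * 58,
            f"track: {self.model.counts.chrom}:{self.model.counts.start}-"
            f"{self.model.counts.end}  ({len(self.model.counts):,} bases, "
            f"{int(self.model.counts.counts.sum()):,} events)",
            f"batches: {len(self.model.batches)}  (min_gap={self.model.min_gap})",
            f"iterations: {self.n_iter}  converged: {self.converged}",
            f"final ELBO: {self.elbo_trace[-1]:.4f}" if len(self.elbo_trace) else "final ELBO: n/a",
            "-" * 58,
            f"{'state':>8} {'r':>3} {'dur_p':>9} {'p_g mean':>10} "
            f"{'95% CI':>19} {'rate/bp':>8}",
        ]
        for i, name in enumerate(defaults.MACRO_STATE_NAMES):
            a, b = self.vb.emission_a[i], self.vb.emission_b[i]
            lo, hi = beta_dist.ppf([0.025, 0.975], a, b)
            lines.append(
                f"{name:>8} {emb.durations[i].r:>3} {emb.durations[i].p:>9.3g} "
                f"{p_mean[i]:>10.4f} [{lo:>8.4f}, {hi:>8.4f}] "
                f"{p_mean[i] / (1 - p_mean[i]):>8.3f}"
            )
        frac_open = float(np.mean(self.posterior.p_open >= 0.5))
        lines.append("-" * 58)
        lines.append(f"fraction of bases with p_open >= 0.5: {frac_open:.4f}")
        return "\n".join(lines)


def fit_hsmm(
    counts: CountTrack,
    max_iter: int = defaults.DEFAULT_MAX_ITER,
    tol: float = defaults.DEFAULT_TOL,
    **model_kwargs,
) -> AccessibilityResults:
    """Convenience wrapper: build the default model on ``counts`` and fit."""
    return AccessibilityHSMM(counts, **model_kwargs).fit(max_iter=max_iter, tol=tol)
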