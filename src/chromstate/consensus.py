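"""Hierarchical consensus accessibility model over replicate experiments.

A shared consensus chain C, itself an NB-duration embedded chain, is
coupled base-by-base to one latent chain S^e per experiment: the effective
transition of experiment e at base b is A^e_{i,j} H_{k,j} with k the
consensus macro-state at b. The link matrix H gives weight lambda to
substates of the macro-state that agrees with the consensus and 1 - lambda
otherwise. Because the link factor depends only on (base, target substate),
it enters the experiment chains as an extra per-base potential, and the
ordinary scaled forward-backward recursion applies to every chain.

Inference is structured mean field over {C} and {S^e}: each outer iteration
refreshes the consensus chain from the experiments' expected link messages,
then each experiment chain (with its conjugate emission updates) from the
consensus marginals; the result therefore does not depend on experiment
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import digamma

from . import defaults
from .embedding import EmbeddedHMM, build_embedding
from .events import Batch, CountTrack, segment_batches
from .exceptions import AlignmentError, ValidationError
from .inference import emission_logpots, macro_marginals, run_forward_backward
from .model import ConvergenceWarning, VBState
from .posterior import PosteriorTrack
from .regions import PeakSet, call_regions


@dataclass
class LinkMatrix:
    """Consensus-to-experiment substate link weights.

    ``H[k, j]`` is the weight of experiment substate j given consensus
    macro-state k: ``coupling`` within the agreeing macro block and
    ``1 - coupling`` elsewhere, so each row aggregated to the two
    experiment macro-states sums to 1.
    """

    H: np.ndarray
    coupling: float


def build_link(coupling: float, substate_macro: np.ndarray, n_macro: int = 2) -> LinkMatrix:
    if not (0.0 < coupling < 1.0):
        raise ValidationError(f"coupling must lie in (0, 1), got {coupling!r}")
    K = len(substate_macro)
    H = np.full((n_macro, K), 1.0 - coupling)
    for k in range(n_macro):
        H[k, np.asarray(substate_macro) == k] = coupling
    return LinkMatrix(H, coupling)


def effective_transition(A: np.ndarray, link: LinkMatrix, k: int) -> np.ndarray:
    """Row-normalized entrywise product A_{i,j} H_{k,j} for consensus state k."""
    M = A * link.H[k][None, :]
    return M / M.sum(axis=1, keepdims=True)


@dataclass
class ConsensusModel:
    consensus: EmbeddedHMM
    experiments: list[EmbeddedHMM]
    link: LinkMatrix


@dataclass
class ConsensusPosterior:
    consensus_track: PosteriorTrack
    experiment_tracks: list[PosteriorTrack]


def build_consensus(
    experiment_specs: Sequence[EmbeddedHMM],
    coupling: float = defaults.DEFAULT_COUPLING,
) -> ConsensusModel:
    """Couple >= 2 experiment embeddings to a fresh consensus chain."""
    experiments = list(experiment_specs)
    if len(experiments) < 2:
        raise ValidationError(
            "consensus needs at least two experiments; fit the single model instead"
        )
    if not (0.5 < coupling < 1.0):
        raise ValidationError(f"coupling must lie in (0.5, 1), got {coupling!r}")
    first = experiments[0]
    for exp in experiments[1:]:
        if not np.array_equal(exp.substate_macro, first.substate_macro):
            raise ValidationError("experiments must share macro-state semantics")
    consensus = build_embedding(
        first.durations,
        first.macro_transition,
        first.emissions,
        first.initial_pseudocounts,
    )
    link = build_link(coupling, first.substate_macro, first.n_macro)
    return ConsensusModel(consensus, experiments, link)


def _expected_pi(emb: EmbeddedHMM, alpha: np.ndarray) -> np.ndarray:
    """Substate initial weights from expected-log Dirichlet pseudocounts."""
    log_pi = digamma(alpha) - digamma(alpha.sum())
    return emb.initial_substate_distribution(np.exp(log_pi))


def fit_consensus(
    model: ConsensusModel,
    tracks: Sequence[CountTrack],
    max_iter: int = 50,
    tol: float = defaults.DEFAULT_TOL,
    min_gap: int = defaults.DEFAULT_MIN_GAP,
    return_state: bool = False,
):
    """Structured mean-field fit of the consensus model.

    Returns a ``ConsensusPosterior``; with ``return_state`` also a
    diagnostics dict (per-experiment VB states, objective trace,
    convergence flag).
    """
    if len(tracks) != len(model.experiments):
        raise ValidationError("one count track per experiment required")
    first = tracks[0]
    for t in tracks[1:]:
        if (t.chrom, t.start, len(t)) != (first.chrom, first.start, len(first)):
            raise AlignmentError("tracks must cover a common span")

    pooled = CountTrack(
        first.chrom, first.start, np.sum([t.counts for t in tracks], axis=0)
    )
    batches = segment_batches(pooled, min_gap)
    if not batches:
        batches = [Batch(pooled.interval, pooled)]
    spans = [
        (b.interval.start - first.start, b.interval.end - first.start) for b in batches
    ]
    xs = [[t.counts[lo:hi] for (lo, hi) in spans] for t in tracks]

    log_H = np.log(model.link.H)  # (n_macro, K)
    cons = model.consensus
    n_exp = len(model.experiments)

    states = [
        VBState(
            np.array([em.prior_a for em in exp.emissions]),
            np.array([em.prior_b for em in exp.emissions]),
            exp.initial_pseudocounts.copy(),
        )
        for exp in model.experiments
    ]
    cons_alpha0 = cons.initial_pseudocounts.astype(float).copy()
    cons_alpha = cons_alpha0.copy()

    # Initialization: one independent E-step per experiment (no link yet).
    gammas: list[list[np.ndarray]] = []
    for e, exp in enumerate(model.experiments):
        log_p, log_1mp = states[e].expected_logs()
        pi = _expected_pi(exp, states[e].initial_alpha)
        gm_batches = []
        for x in xs[e]:
            logpots = emission_logpots(x, exp.substate_macro, log_p, log_1mp)
            gamma, _ = run_forward_backward(logpots, exp.transition, pi)
            gm_batches.append(gamma)
        gammas.append(gm_batches)

    objective: list[float] = []
    converged = False
    gamma_c_macro: list[np.ndarray] = []
    for _ in range(max_iter):
        # --- consensus chain: link messages from all experiments ---------
        cons_pi = _expected_pi(cons, cons_alpha)
        gamma_c_macro = []
        log_z_total = 0.0
        cons_init = np.zeros(cons.n_macro)
        for bi in range(len(batches)):
            B = spans[bi][1] - spans[bi][0]
            msg = np.zeros((B, cons.n_macro))
            for e in range(n_exp):
                msg += gammas[e][bi] @ log_H.T
            logpots_c = msg[:, cons.substate_macro]
            gamma_c, log_z = run_forward_backward(logpots_c, cons.transition, cons_pi)
            gm = macro_marginals(cons, gamma_c)
            gamma_c_macro.append(gm)
            cons_init += gm[0]
            log_z_total += log_z
        cons_alpha = cons_alpha0 + cons_init

        # --- experiment chains: link potential from consensus marginals --
        for e, exp in enumerate(model.experiments):
            log_p, log_1mp = states[e].expected_logs()
            pi = _expected_pi(exp, states[e].initial_alpha)
            a0 = np.array([em.prior_a for em in exp.emissions])
            b0 = np.array([em.prior_b for em in exp.emissions])
            nx = np.zeros(exp.n_macro)
            n = np.zeros(exp.n_macro)
            init_counts = np.zeros(exp.n_macro)
            for bi, x in enumerate(xs[e]):
                logpots = emission_logpots(x, exp.substate_macro, log_p, log_1mp)
                logpots += gamma_c_macro[bi] @ log_H
                gamma, log_z = run_forward_backward(logpots, exp.transition, pi)
                gammas[e][bi] = gamma
                gm = macro_marginals(exp, gamma)
                nx += gm.T @ x
                n += gm.sum(axis=0)
                init_counts += gm[0]
                log_z_total += log_z
            states[e].emission_a = a0 + nx
            states[e].emission_b = b0 + n
            states[e].initial_alpha = exp.initial_pseudocounts + init_counts

        objective.append(log_z_total)
        if len(objective) >= 2:
            prev = objective[-2]
            if abs(objective[-1] - prev) <= tol * max(1.0, abs(prev)):
                converged = True
                break

    if not converged:
        warnings.warn(
            f"consensus fit did not converge in {max_iter} iterations",
            ConvergenceWarning,
        )

    n_bases = len(first)
    cons_open = np.zeros(n_bases)
    exp_open = [np.zeros(n_bases) for _ in range(n_exp)]
    for bi, (lo, hi) in enumerate(spans):
        cons_open[lo:hi] = gamma_c_macro[bi][:, 1]
        for e, exp in enumerate(model.experiments):
            exp_open[e][lo:hi] = macro_marginals(exp, gammas[e][bi])[:, 1]
    np.clip(cons_open, 0.0, 1.0, out=cons_open)
    for po in exp_open:
        np.clip(po, 0.0, 1.0, out=po)

    posterior = ConsensusPosterior(
        consensus_track=PosteriorTrack(first.chrom, first.start, cons_open),
        experiment_tracks=[
            PosteriorTrack(first.chrom, first.start, po) for po in exp_open
        ],
    )
    if return_state:
        diagnostics = {
            "states": states,
            "consensus_alpha": cons_alpha,
            "objective": np.asarray(objective),
            "converged": converged,
            "n_batches": len(batches),
        }
        return posterior, diagnostics
    return posterior


class ConsensusHSMM:
    """Model object over aligned replicate count tracks.

    Builds one embedding per experiment (shared structure) plus the
    consensus chain; ``fit`` returns a :class:`ConsensusResults`.
    """

    def __init__(
        self,
        tracks: Sequence[CountTrack],
        coupling: float = defaults.DEFAULT_COUPLING,
        min_gap: int = defaults.DEFAULT_MIN_GAP,
        **embedding_kwargs,
    ):
        from .model import AccessibilityHSMM

        if len(tracks) < 2:
            raise ValidationError(
                "consensus needs at least two experiments; fit the single model instead"
            )
        self.tracks = list(tracks)
        self.min_gap = min_gap
        template = AccessibilityHSMM(tracks[0], min_gap=min_gap, **embedding_kwargs)
        experiments = [
            AccessibilityHSMM(t, min_gap=min_gap, **embedding_kwargs).embedding
            for t in tracks
        ]
        self.consensus_model = ConsensusModel(
            consensus=build_embedding(
                template.embedding.durations,
                template.embedding.macro_transition,
                template.embedding.emissions,
                template.embedding.initial_pseudocounts,
            ),
            experiments=experiments,
            link=build_link(
                coupling, template.embedding.substate_macro, template.embedding.n_macro
            ),
        )
        if not (0.5 < coupling < 1.0):
            raise ValidationError(f"coupling must lie in (0.5, 1), got {coupling!r}")

    def fit(self, max_iter: int = 50, tol: float = defaults.DEFAULT_TOL) -> "ConsensusResults":
        posterior, diag = fit_consensus(
            self.consensus_model,
            self.tracks,
            max_iter=max_iter,
            tol=tol,
            min_gap=self.min_gap,
            return_state=True,
        )
        return ConsensusResults(self, posterior, diag)


@dataclass
class ConsensusResults:
    model: ConsensusHSMM
    posterior: ConsensusPosterior
    diagnostics: dict

    @property
    def consensus_track(self) -> PosteriorTrack:
        return self.posterior.consensus_track

    @property
    def experiment_tracks(self) -> list[PosteriorTrack]:
        return self.posterior.experiment_tracks

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics["converged"])

    def call_consensus_regions(
        self,
        threshold: float = defaults.DEFAULT_POSTERIOR_THRESHOLD,
        min_length: int = defaults.DEFAULT_MIN_REGION_LENGTH,
    ) -> PeakSet:
        return call_regions(self.consensus_track, threshold, min_length)

    def call_experiment_regions(
        self,
        index: int,
        threshold: float = defaults.DEFAULT_POSTERIOR_THRESHOLD,
        min_length: int = defaults.DEFAULT_MIN_REGION_LENGTH,
    ) -> PeakSet:
        return call_regions(
            self.experiment_tracks[index],
            threshold,
            min_length,
            counts=self.model.tracks[index],
        )

    def summary(self) -> str:
        lines = [
            "Consensus accessibility fit (structured mean field)",
            "=" * 58,
            f"experiments: {len(self.model.tracks)}  "
            f"coupling lambda: {self.model.consensus_model.link.coupling}",
            f"outer iterations: {len(self.diagnostics['objective'])}  "
            f"converged: {self.converged}",
            f"batches: {self.diagnostics['n_batches']}",
        ]
        for e, st in enumerate(self.diagnostics["states"]):
            p = st.emission_posterior_mean
            lines.append(
                f"  experiment {e}: p_g(closed)={p[0]:.4f}  p_g(open)={p[1]:.4f}"
            )
        frac = float(np.mean(self.consensus_track.p_open >= 0.5))
        lines.append(f"consensus fraction open (p >= 0.5): {frac:.4f}")
        return "\n".join(lines)
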