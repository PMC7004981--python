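"""HMM embedding of the negative-binomial-duration semi-Markov chain.

A two-state semi-Markov chain over (closed, open) chromatin with NB(r_i,
p_i) sojourns is rewritten as an ordinary Markov chain over
r_closed + r_open *substates*. Each substate self-loops with probability
1 - p_i and advances with p_i; leaving the last substate of macro-state m,
the chain picks the next macro-state n from the macro transition matrix
``a`` and enters substate j of n with Binomial(j; r_n - 1, p_n) weight.
The induced macro-state sojourn law is exactly the NB duration pmf, and
standard HMM forward-backward machinery applies at O(r) cost per state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import defaults
from .durations import NBDurationSpec, entry_weights
from .emissions import GeometricEmission
from .exceptions import ValidationError

_ROW_SUM_TOL = 1e-12


@dataclass
class EmbeddedHMM:
    """The embedded chain: substate transition matrix plus priors.

    ``substate_macro[k]`` maps substate k to its macro-state (0 closed,
    1 open); substates are laid out closed block first.
    """

    durations: tuple[NBDurationSpec, NBDurationSpec]
    macro_transition: np.ndarray
    transition: np.ndarray
    substate_macro: np.ndarray
    emissions: tuple[GeometricEmission, GeometricEmission]
    initial_pseudocounts: np.ndarray

    @property
    def n_substates(self) -> int:
        return self.transition.shape[0]

    @property
    def n_macro(self) -> int:
        return len(self.durations)

    def macro_blocks(self) -> list[np.ndarray]:
        """Substate indices of each macro-state block."""
        return [np.flatnonzero(self.substate_macro == m) for m in range(self.n_macro)]

    def entry_distribution(self) -> list[np.ndarray]:
        """Binomial entry weights of each macro block (sums to 1 each)."""
        return [entry_weights(spec) for spec in self.durations]

    def initial_substate_distribution(self, pi_macro: np.ndarray | None = None) -> np.ndarray:
        """Spread a macro-level initial law over substates via entry weights."""
        if pi_macro is None:
            alpha = np.asarray(self.initial_pseudocounts, dtype=float)
            pi_macro = alpha / alpha.sum()
        pi = np.zeros(self.n_substates)
        for m, (block, w) in enumerate(zip(self.macro_blocks(), self.entry_distribution())):
            pi[block] = pi_macro[m] * w
        return pi

    def validate(self) -> None:
        rows = self.transition.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=_ROW_SUM_TOL, rtol=0):
            raise ValidationError("embedded transition rows must sum to 1")
        if len(self.substate_macro) != self.n_substates:
            raise ValidationError("substate-to-macro map must be total")


def build_embedding(
    durations: tuple[NBDurationSpec, NBDurationSpec],
    macro_transition: np.ndarray | None = None,
    emissions: tuple[GeometricEmission, GeometricEmission] | None = None,
    initial_pseudocounts=defaults.INITIAL_PSEUDOCOUNTS,
) -> EmbeddedHMM:
    """Construct the embedded HMM for a (closed, open) NB-duration chain.

    ``macro_transition`` defaults to the two-state alternating matrix
    [[0, 1], [1, 0]] (a semi-Markov chain re-enters a different state after
    each sojourn).
    """
    if macro_transition is None:
        macro_transition = np.array([[0.0, 1.0], [1.0, 0.0]])
    a = np.asarray(macro_transition, dtype=float)
    n_macro = len(durations)
    if a.shape != (n_macro, n_macro):
        raise ValidationError(f"macro transition must be {n_macro}x{n_macro}")
    if (a < 0).any() or not np.allclose(a.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError("macro transition must be row-stochastic")
    if emissions is None:
        emissions = (
            GeometricEmission(
                defaults.CLOSED_EMISSION_PRIOR[0]
                / (defaults.CLOSED_EMISSION_PRIOR[0] + defaults.CLOSED_EMISSION_PRIOR[1]),
                *defaults.CLOSED_EMISSION_PRIOR,
            ),
            GeometricEmission(
                defaults.OPEN_EMISSION_PRIOR[0]
                / (defaults.OPEN_EMISSION_PRIOR[0] + defaults.OPEN_EMISSION_PRIOR[1]),
                *defaults.OPEN_EMISSION_PRIOR,
            ),
        )

    rs = [spec.r for spec in durations]
    K = sum(rs)
    offsets = np.concatenate([[0], np.cumsum(rs)])
    substate_macro = np.repeat(np.arange(n_macro), rs)
    weights = [entry_weights(spec) for spec in durations]

    A = np.zeros((K, K))
    for m, spec in enumerate(durations):
        o = offsets[m]
        for i in range(spec.r):
            A[o + i, o + i] = 1.0 - spec.p  # self-loop: dwell another base
            if i < spec.r - 1:
                A[o + i, o + i + 1] = spec.p
        # Exit from the last substate: macro transition times binomial entry.
        last = o + spec.r - 1
        for n in range(n_macro):
            if a[m, n] == 0.0:
                continue
            A[last, offsets[n] : offsets[n] + rs[n]] += spec.p * a[m, n] * weights[n]

    model = EmbeddedHMM(
        durations=tuple(durations),
        macro_transition=a,
        transition=A,
        substate_macro=substate_macro,
        emissions=tuple(emissions),
        initial_pseudocounts=np.asarray(initial_pseudocounts, dtype=float),
    )
    model.validate()
    return model


def sojourn_pmf(model: EmbeddedHMM, macro: int, d_max: int) -> np.ndarray:
    """Closed-form sojourn law of a macro-state implied by the substate chain.

    Treats the macro block as a transient phase-type chain: start from the
    binomial entry weights, propagate through the intra-block transition
    submatrix, absorb with the block's exit mass. Returns P(d) for
    d = 1..d_max; equals ``nb_duration_pmf`` by construction (this is the
    diagnostic used to verify that equality).
    """
    block = model.macro_blocks()[macro]
    T = model.transition[np.ix_(block, block)]
    exit_prob = 1.0 - T.sum(axis=1)
    w = model.entry_distribution()[macro]
    pmf = np.empty(d_max)
    v = w.copy()
    for d in range(d_max):
        pmf[d] = v @ exit_prob
        v = v @ T
    return pmf
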