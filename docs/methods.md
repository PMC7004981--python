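# Methods

## Model

Chromatin state at base *b* of a chromosome is a binary latent variable
S_b (0 = closed, 1 = open). State dwell times are negative-binomial:

    d ~ NB(r, p):  P(d = l + 1 | r, p) = C(l + r - 1, l) p^r (1 - p)^l,  l >= 0

with mean 1 + r(1 - p)/p and a mode away from 1 for r > 1, unlike the
geometric dwell law of an ordinary HMM. The chain alternates strictly
between the two states (macro transition [[0, 1], [1, 0]]).

We use the standard embedding of an NB-duration semi-Markov chain into an
HMM: macro-state *i* becomes r_i substates, each self-looping with
probability 1 - p_i and advancing with p_i; the exit from the last
substate enters the next macro-state's substate *j* with binomial weight
Binom(j; r - 1, p). The induced sojourn law equals the NB pmf *exactly*
(`sojourn_pmf` computes it in closed form from the substate chain and the
tests verify termwise agreement to < 1e-10). Note one parameterization
trap: with pmf as above, p is the per-substate *advance* probability and
the self-loop is 1 - p; an equivalent convention swaps p and 1 - p. We
follow the pmf above everywhere; under it the fixed default p = 1e-4
yields biologically plausible multi-kilobase dwells (closed ~5e4, open
~2e4 bases in expectation). Its mode over l sits at (1 - p)(r - 1)/p.

Counts of Tn5 insertion events per base are geometric,
P(x | p_g) = p_g^x (1 - p_g), mean p_g/(1 - p_g). The geometric is a
deliberately heavy-tailed, low-assumption choice: the number of cells
sampled and the per-cell insertion opportunities are unknown, so only the
per-base rate scale is modeled. Conjugate Beta(a0, b0) priors per state:
(1, 50) closed and (20, 10) open, i.e. prior mean rates 0.02 and 2.0
events/base; inference is insensitive to these within wide ranges because
genome-scale counts dominate the pseudocounts after one iteration.

## Fixed parameters and defaults

| parameter | default | units / meaning |
|---|---|---|
| substates r (closed, open) | 5, 2 | NB shape per state |
| duration p | 1e-4 | per-substate advance probability (fixed, not learned) |
| emission priors | (1,50), (20,10) | Beta pseudocounts per state |
| initial pseudocounts | (1000, 1) | Dirichlet over (closed, open) at batch starts |
| min_gap | 5000 bp | zero run separating inference batches |
| posterior threshold | 0.05 | p_open cut for region calls |
| min region length | 50 bp | suppresses single-base calls |
| consensus coupling λ | 0.7 | link strength, see below |
| Tn5 offsets | +4 / −5 bp | plus/minus strand 5' shift (atac mode) |
| promoter window | −1000 / +3000 bp | strand-aware, for the SNR metric |
| max_iter / tol | 100 / 1e-6 | VB stopping rule (relative ELBO change) |

The substate allocation assigns the larger r to the closed state; both
are constructor arguments. The 0.05 threshold is applied to the *open*
posterior (p_open >= 0.05, ties included); `call_regions(on="closed")`
switches to thresholding the closed posterior instead.

## Inference

Mean-field variational Bayes with conjugate updates. Each iteration runs
the scaled forward-backward recursion under expected-log parameters
(digamma differences of the current Beta/Dirichlet pseudocounts), then
updates pseudocounts from the expected sufficient statistics. The ELBO —
the sum of scaled-recursion log-normalizers minus the Beta and Dirichlet
KL terms — is non-decreasing by construction; the tests assert this to a
1e-8 tolerance. The transition matrix is fixed (duration p and the
alternating macro transition are not learned), following the design of
keeping duration structure as a modeling choice rather than a fitted
quantity.

Numerics: per-base potentials are computed in log space and shifted by
their per-base maximum before the linear-space scaled recursion, so
arbitrarily unlikely counts cannot underflow; the recursion reports the
first base index at which a scaling constant degenerates. The hot loop is
a numba kernel; 1e6 bases x 7 substates runs in well under a second per
sweep.

### Batches

Inference runs on batches delimited by zero-count runs >= min_gap, each
batch starting from the closed-favoring initial law. This is an
approximation: the whole-track log-evidence exceeds the batch sum by
exactly log(lambda_max(A diag(e0))) per gap base (the zero-run likelihood
rate; verified in the tests via the dominant eigenvalue) plus an O(1)
boundary constant, because the batch initial distribution (binomial entry
weights) differs from the chain's quasi-stationary substate phase after a
long gap. In-batch posteriors agree with the whole-track computation to
~1e-3 near batch edges and much better elsewhere; bases inside removed
gaps are reported closed with p_open = 0. An all-zero track is fitted as
a single batch so the prior-driven posterior is still computed.

## Consensus model

The consensus chain C carries the same NB-duration embedding. Experiment
chains S^e gain a per-base dependency on C: the transition factor is
A^e_ij H_kj, where H_kj = λ for substates j of the macro-state agreeing
with consensus state k and 1 − λ otherwise. Because the link factor
depends only on (base, target substate), it folds into the per-base
potential and the same forward-backward kernel serves every chain.
Structured mean field alternates: consensus chain first (its per-base
potential is the sum over experiments of expected log H), then each
experiment chain (with its own conjugate emission updates) against the
fresh consensus marginals — the result is exactly invariant to experiment
order, and λ = 0.5 decouples the hierarchy (the link adds a constant),
recovering the single-experiment fit to machine precision.

H is constant within each macro block rather than divided by the block
size: division would add a j-dependent offset −log r_macro(j) to every
experiment transition, a permanent bias toward the smaller block that has
nothing to do with the consensus and would break the λ = 0.5 decoupling.
An alternative reading renormalizes A^e_ij H_kj per row; we expose it as
`effective_transition` (and test its normalization), but do not use it
for inference: exact row renormalization cancels the link inside macro
blocks, leaving the consensus informed only at transition bases, which
makes it unresponsive to the replicates in practice.

### Choice of λ = 0.7

The link contributes log(λ/(1−λ)) nats per base wherever the consensus is
confident. At the emission prior means, one zero-count base carries about
1.01 nats of evidence for closed over open. A coupling of 0.85
(log-odds 1.73) therefore lets a confident consensus *override* an
experiment's own flat signal, copying consensus regions into a
discordant replicate; at 0.7 (log-odds 0.85) the link reinforces but
cannot override per-base data. We verified both regimes by simulation:
with two concordant replicates plus one outlier, λ = 0.85 drives the
outlier's region-level F1 against its own truth down to 0.68–0.82, while
λ = 0.7 keeps it at ~1.0 with no loss of consensus agreement. The default
is therefore 0.7; λ is a constructor/CLI argument. Convergence of the
consensus fit is monitored on the summed chain log-normalizers (a
heuristic: the structured bound's cross terms are not assembled into a
single ELBO), with a warning on non-convergence.

## Input conventions

Coordinates are 0-based half-open everywhere internally; BED I/O is
as-is. For alignments, one event per read: the plus-strand 5' start
shifted +4 bp, the minus-strand 5' end (its highest aligned base) shifted
−5 bp; `dnase` mode disables the shift. Unmapped, secondary and
supplementary records are skipped and counted in the log. TSV rows
(chrom, start, end, optional barcode, optional strand/count) are taken to
list already-corrected events, one event per row at `start`; this makes
write-then-read an exact round trip. Cell Ranger fragment files, in which
both fragment ends are insertions, are supported with
`fragment_ends="both"` (events at start and end−1). Barcodes are
preserved on ingestion and pooled when counting. Blacklist filtering
removes events whose position falls inside any interval (half-open).

## Synthetic data

The simulator draws states from the alternating NB-sojourn process and
counts from the per-state geometric — exactly the generative model — so
recovery tests are well-posed. Default conditions are the model's
operating point: r = (5, 2), duration p = 1e-4, emissions at the prior
means (0.02 / 2.0 events per base). Single-cell-style fragment records
attach each event to a fragment start, a partner end at a bimodal insert
length (normal modes ~70 ± 8 and ~200 ± 12 bp, equal weight, mimicking
nucleosome-free and mono-nucleosome fragments) and a uniformly assigned
cell barcode, so TSV ingestion, pooling, downsampling and the insert-size
metric are all exercisable. What the simulator does *not* emulate: local
sequence and GC bias, mappability gaps, duplicated reads, nucleosome
phasing within open regions, and overdispersion beyond the geometric —
passing recovery tests therefore demonstrates correctness of the
inference machinery under the model's own assumptions, not robustness to
every artifact of real libraries.

Problem sizes in the test suite and acceptance script (1e6 bases for
recovery, 3e5 for consensus and threshold sweeps, 1e6 Monte-Carlo
sojourns, tracks <= 10 bases for exhaustive enumeration) were chosen so
each check is statistically decisive while the whole suite stays
desk-scale.

## QC and benchmarking conventions

FRIP counts properly paired, mated reads (standard flag semantics) on
chromosome 1 overlapping any called peak. The promoter SNR uses
strand-aware windows (1 kb upstream, 3 kb downstream of gene starts)
against the remaining chromosome as background; a zero background with
nonzero promoter signal reports infinity with a capped flag. The
insert-size ratio is count(190-210 bp) / count(60-80 bp), bounds
inclusive. Dynamic range is log2(max/min nonzero per-base count) — a
convention for summarizing count depth in bits, not a formula with an
external definition. Reference-region metrics: fpc (fraction of reference
peaks with any overlap), apc (mean +/- s.e.m. of per-peak covered
fraction), tc (pooled covered-base fraction; algebraically the
length-weighted mean of the per-peak fractions). Summit metrics report
precision (peaks containing >= 1 summit), recall as both a raw
overlapping-summit count and a fraction, and the F1 harmonic mean of the
two fractions — F1 needs a rate, so the fraction form is used there while
the raw count is still reported. All overlap tests are half-open; a
summit at a peak's end coordinate is outside.

## Known limitations

- Two macro-states only; no per-base covariates; r is fixed, not selected.
- The batch approximation trades a bounded edge effect (~1e-3 posterior
  error near batch boundaries) for memory and speed.
- The consensus objective is a monitoring quantity, not a certified bound.
- Chromosome tracks are dense arrays; a full mammalian chromosome at
  1 bp resolution costs ~1.6 GB per track in counts plus the posterior.
- QC metrics beyond dynamic range require paired alignments (BAM/SAM);
  fragment TSVs provide insert sizes but no pairing flags.
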