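"""Package-wide default parameters.

These are the fixed constants of the accessibility model: the Tn5
event-center offsets applied to read 5' ends, the conjugate priors of the
two-state emission model, the substate allocation of the negative-binomial
duration embedding, and the posterior threshold used to call regions.
"""

# Tn5 dimer footprint correction: the transposase inserts two adaptors 9 bp
# apart, so 5' read starts are shifted towards the dimer center.
ATAC_PLUS_OFFSET = 4
ATAC_MINUS_OFFSET = -5

# Macro-state order everywhere: index 0 = closed, index 1 = open.
CLOSED, OPEN = 0, 1
MACRO_STATE_NAMES = ("closed", "open")

# Substates of the negative-binomial duration embedding (r parameters).
CLOSED_SUBSTATES = 5
OPEN_SUBSTATES = 2

# Per-substate advance probability of the duration chain; the NB(r, p)
# sojourn mean is 1 + r (1-p)/p, so 1e-4 gives multi-kilobase dwells.
DEFAULT_DURATION_P = 1e-4

# Beta pseudocounts (a0, b0) of the geometric emission p(x) = p_g^x (1-p_g):
# closed chromatin expects ~0.02 events/base, open ~2 events/base.
CLOSED_EMISSION_PRIOR = (1.0, 50.0)
OPEN_EMISSION_PRIOR = (20.0, 10.0)

# Dirichlet pseudocounts over (closed, open) for the initial state of each
# batch; batches start after long empty stretches, hence closed-dominant.
INITIAL_PSEUDOCOUNTS = (1000.0, 1.0)

# Minimum zero-count run separating inference batches.
DEFAULT_MIN_GAP = 5000

# Posterior p_open threshold and minimum run length for region calling.
DEFAULT_POSTERIOR_THRESHOLD = 0.05
DEFAULT_MIN_REGION_LENGTH = 50

# Consensus link strength lambda in (0.5, 1). Chosen so the per-base link
# log-odds log(lambda/(1-lambda)) ~ 0.85 stays below the ~1.0-nat per-base
# evidence a zero count carries for closed chromatin at the prior means:
# a confident consensus then reinforces but cannot override an
# experiment's own data, keeping outlier replicates unperturbed.
DEFAULT_COUPLING = 0.7

# Promoter window around gene starts for the signal-to-noise QC metric
# (strand-aware: upstream is against gene orientation).
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 3000

# Variational fit controls.
DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-6


def default_config() -> dict:
    """Model configuration as a flat key-value mapping."""
    return {
        "atac_plus_offset": ATAC_PLUS_OFFSET,
        "atac_minus_offset": ATAC_MINUS_OFFSET,
        "closed_substates": CLOSED_SUBSTATES,
        "open_substates": OPEN_SUBSTATES,
        "duration_p_closed": DEFAULT_DURATION_P,
        "duration_p_open": DEFAULT_DURATION_P,
        "closed_emission_a0": CLOSED_EMISSION_PRIOR[0],
        "closed_emission_b0": CLOSED_EMISSION_PRIOR[1],
        "open_emission_a0": OPEN_EMISSION_PRIOR[0],
        "open_emission_b0": OPEN_EMISSION_PRIOR[1],
        "initial_closed": INITIAL_PSEUDOCOUNTS[0],
        "initial_open": INITIAL_PSEUDOCOUNTS[1],
        "min_gap": DEFAULT_MIN_GAP,
        "posterior_threshold": DEFAULT_POSTERIOR_THRESHOLD,
        "min_region_length": DEFAULT_MIN_REGION_LENGTH,
        "coupling": DEFAULT_COUPLING,
        "promoter_upstream": PROMOTER_UPSTREAM,
        "promoter_downstream": PROMOTER_DOWNSTREAM,
        "max_iter": DEFAULT_MAX_ITER,
        "tol": DEFAULT_TOL,
    }


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        for key, value in config.items():
            fh.write(f"{key} = {value}\n")


def load_config(path) -> dict:
    """Read a flat ``key = value`` config file, numbers parsed as such."""
    out = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            value = value.strip()
            try:
                parsed = int(value)
            except ValueError:
                try:
                    parsed = float(value)
                except ValueError:
                    parsed = value
            out[key.strip()] = parsed
    return out
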