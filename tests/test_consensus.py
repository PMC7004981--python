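"""Consensus model: link matrix, decoupling, robustness, invariances."""

import numpy as np
import pytest

from chromstate import (
    AccessibilityHSMM,
    ConsensusHSMM,
    CountTrack,
    SimulationConfig,
    base_level_f1,
    build_consensus,
    build_link,
    effective_transition,
    fit_consensus,
    sample_generative,
)
from chromstate.consensus import ConsensusModel
from chromstate.durations import NBDurationSpec
from chromstate.embedding import build_embedding
from chromstate.exceptions import AlignmentError, ValidationError

SHORT_DURS = (NBDurationSpec(5, 5e-4), NBDurationSpec(2, 6.7e-4))


def _replicate_counts(states, emission_p, seed):
    rng = np.random.default_rng(seed)
    c = np.empty(len(states), dtype=np.int64)
    for s, p in enumerate(emission_p):
        mask = states == s
        c[mask] = rng.geometric(1.0 - p, size=int(mask.sum())) - 1
    return CountTrack("chr1", 0, c)


@pytest.fixture(scope="module")
def replicate_setup():
    cfg = SimulationConfig(n_bases=200_000, seed=3, durations=SHORT_DURS)
    ds = sample_generative(cfg)
    t1 = _replicate_counts(ds.truth_states, cfg.emission_p, 100)
    t2 = _replicate_counts(ds.truth_states, cfg.emission_p, 101)
    outlier_cfg = SimulationConfig(n_bases=200_000, seed=93, durations=SHORT_DURS)
    ds_out = sample_generative(outlier_cfg)
    t3 = _replicate_counts(ds_out.truth_states, cfg.emission_p, 102)
    return ds, ds_out, t1, t2, t3


class TestLinkMatrix:
    def test_rows_aggregate_to_coupling(self):
        sm = np.array([0] * 5 + [1] * 2)
        link = build_link(0.85, sm)
        assert link.H.shape == (2, 7)
        # aggregated to experiment macro-states each row sums to 1
        for k in range(2):
            agg = [link.H[k, sm == m].max() for m in range(2)]
            assert agg[k] == pytest.approx(0.85)
            assert agg[1 - k] == pytest.approx(0.15)

    def test_effective_transition_rows_sum_to_one(self, default_embedding, rng):
        link = build_link(0.7, default_embedding.substate_macro)
        for k in range(2):
            M = effective_transition(default_embedding.transition, link, k)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_strong_coupling_copies_consensus_macro_state(self, default_embedding):
        """In the lambda -> 1 limit the experiment chain is forced onto the
        consensus macro-state."""
        link = build_link(1 - 1e-12, default_embedding.substate_macro)
        for k in range(2):
            M = effective_transition(default_embedding.transition, link, k)
            agree = default_embedding.substate_macro == k
            # from any substate with an allowed move into the agreeing
            # block, virtually all mass lands there
            mass = M[:, agree].sum(axis=1)
            reachable = (default_embedding.transition[:, agree] > 0).any(axis=1)
            assert (mass[reachable] > 1 - 1e-6).all()

    def test_half_coupling_is_uninformative(self, default_embedding):
        link = build_link(0.5, default_embedding.substate_macro)
        M0 = effective_transition(default_embedding.transition, link, 0)
        M1 = effective_transition(default_embedding.transition, link, 1)
        np.testing.assert_allclose(M0, M1, atol=1e-15)
        np.testing.assert_allclose(M0, default_embedding.transition, atol=1e-15)


class TestBuildConsensus:
    def test_single_experiment_refused(self, default_embedding):
        with pytest.raises(ValidationError, match="single model"):
            build_consensus([default_embedding], 0.85)

    def test_coupling_range_enforced(self, default_embedding):
        with pytest.raises(ValidationError):
            build_consensus([default_embedding, default_embedding], 0.4)


class TestFitConsensus:
    def test_single_chain_half_coupling_equals_single_fit(self):
        """One experiment with lambda = 0.5 decouples: the experiment
        posterior equals the single-model fit within 1e-8."""
        ds = sample_generative(
            SimulationConfig(n_bases=50_000, seed=3, durations=SHORT_DURS)
        )
        emb = AccessibilityHSMM(ds.counts).embedding
        link = build_link(0.5, emb.substate_macro)
        cons = build_embedding(
            emb.durations, emb.macro_transition, emb.emissions, emb.initial_pseudocounts
        )
        model = ConsensusModel(cons, [emb], link)
        post = fit_consensus(model, [ds.counts])
        single = AccessibilityHSMM(ds.counts).fit()
        np.testing.assert_allclose(
            post.experiment_tracks[0].p_open, single.posterior.p_open, atol=1e-8
        )

    def test_identical_replicates_match_single_fit(self, replicate_setup):
        ds, _, t1, _, _ = replicate_setup
        res = ConsensusHSMM([t1, t1]).fit()
        single = AccessibilityHSMM(t1).fit()
        mad = np.abs(res.consensus_track.p_open - single.posterior.p_open).mean()
        assert mad < 0.05

    def test_outlier_keeps_private_regions_consensus_tracks_pair(self, replicate_setup):
        ds, ds_out, t1, t2, t3 = replicate_setup
        res = ConsensusHSMM([t1, t2, t3]).fit()
        res_pair = ConsensusHSMM([t1, t2]).fit()
        n = len(t1)

        def mask(track):
            return track.p_open >= 0.05

        # consensus with the outlier matches the concordant-only consensus
        inter = (mask(res.consensus_track) & mask(res_pair.consensus_track)).sum()
        union = (mask(res.consensus_track) | mask(res_pair.consensus_track)).sum()
        assert inter / union >= 0.9
        # outlier's own chain still finds its private truth
        f1 = base_level_f1(ds_out.truth_mask, mask(res.experiment_tracks[2]))
        assert f1 >= 0.8

    def test_permutation_invariance(self, replicate_setup):
        _, _, t1, t2, t3 = replicate_setup
        a = ConsensusHSMM([t1, t2, t3]).fit()
        b = ConsensusHSMM([t3, t1, t2]).fit()
        np.testing.assert_allclose(
            a.consensus_track.p_open, b.consensus_track.p_open, atol=1e-9
        )
        np.testing.assert_allclose(
            a.experiment_tracks[0].p_open, b.experiment_tracks[1].p_open, atol=1e-9
        )

    def test_all_zero_tracks_stay_closed(self):
        z = CountTrack("chr1", 0, np.zeros(2000, dtype=np.int64))
        res = ConsensusHSMM([z, z]).fit()
        assert (res.consensus_track.p_open < 0.05).all()

    def test_misaligned_tracks_rejected(self):
        t1 = CountTrack("chr1", 0, np.ones(100, dtype=np.int64))
        t2 = CountTrack("chr1", 50, np.ones(100, dtype=np.int64))
        with pytest.raises(AlignmentError):
            ConsensusHSMM([t1, t2]).fit()

    def test_outlier_does_not_reduce_replicate_correlation(self, replicate_setup):
        """Tn5-count correlation between concordant replicates over
        consensus regions is unchanged (within 0.01) by adding an outlier."""
        from chromstate.regions import count_events_in_regions

        _, _, t1, t2, t3 = replicate_setup
        res_pair = ConsensusHSMM([t1, t2]).fit()
        res_trio = ConsensusHSMM([t1, t2, t3]).fit()
        for res in (res_pair, res_trio):
            peaks = res.call_consensus_regions()
            c1 = count_events_in_regions(peaks, t1)
            c2 = count_events_in_regions(peaks, t2)
            res.corr = float(np.corrcoef(c1, c2)[0, 1])
        assert res_trio.corr >= res_pair.corr - 0.01
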