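"""Event ingestion: offset correction, blacklist filtering, tracks, batches."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromstate.events import (
    CountTrack,
    Tn5Event,
    build_count_track,
    filter_blacklisted,
    read_tn5_events,
    segment_batches,
    write_events_tsv,
)
from chromstate.exceptions import InputFormatError, OutOfBoundsError
from chromstate.intervals import GenomicInterval

from _oracles import brute_blacklist_mask


class TestOffsetCorrection:
    @pytest.mark.parametrize(
        "flag,pos,length,mode,expected",
        [
            (0, 100, 50, "atac", 104),    # plus strand: 5' start + 4
            (16, 151, 50, "atac", 195),   # minus strand: 5' end (200) - 5
            (0, 100, 50, "dnase", 100),   # dnase: no shift
            (16, 151, 50, "dnase", 200),
        ],
    )
    def test_read_center_correction(self, sam_factory, flag, pos, length, mode, expected):
        path = sam_factory([{"flag": flag, "pos": pos, "length": length}])
        events = read_tn5_events(path, mode=mode)
        assert [ev.pos for ev in events] == [expected]

    def test_offsets_antisymmetric_in_atac_identity_in_dnase(self, sam_factory):
        # A plus and a minus read with the same 5' coordinate move in
        # opposite directions under atac correction and not at all in dnase.
        path = sam_factory(
            [{"flag": 0, "pos": 300, "length": 50}, {"flag": 16, "pos": 251, "length": 50}]
        )
        atac = sorted(ev.pos for ev in read_tn5_events(path, mode="atac"))
        dnase = sorted(ev.pos for ev in read_tn5_events(path, mode="dnase"))
        assert dnase == [300, 300]
        assert atac == [295, 304]  # 300 - 5 and 300 + 4

    def test_unmapped_and_secondary_skipped(self, sam_factory):
        path = sam_factory(
            [{"flag": 4, "pos": 10}, {"flag": 256, "pos": 20}, {"flag": 0, "pos": 30}]
        )
        assert len(read_tn5_events(path)) == 1

    def test_unreadable_source_raises_input_format_error(self, tmp_path):
        bad = tmp_path / "bad.bam"
        bad.write_bytes(b"this is not a BAM")
        with pytest.raises(InputFormatError):
            read_tn5_events(str(bad))


class TestBlacklist:
    def test_event_inside_blacklist_removed(self, sam_factory):
        path = sam_factory([{"flag": 0, "pos": 100, "length": 50}])  # event at 104
        bl = [GenomicInterval("chr1", 100, 110)]
        assert read_tn5_events(path, blacklist=bl) == []

    @given(
        positions=st.lists(st.integers(0, 500), min_size=1, max_size=60),
        ivs=st.lists(
            st.tuples(st.integers(0, 480), st.integers(1, 40)), min_size=1, max_size=8
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_per_event_brute_force(self, positions, ivs):
        events = [Tn5Event("chr1", p) for p in positions]
        blacklist = [GenomicInterval("chr1", s, s + w) for s, w in ivs]
        kept = filter_blacklisted(events, blacklist)
        mask = brute_blacklist_mask(events, blacklist)
        expected = [ev for ev, hit in zip(events, mask) if not hit]
        assert kept == expected

    def test_half_open_boundaries(self):
        bl = [GenomicInterval("chr1", 10, 20)]
        events = [Tn5Event("chr1", 9), Tn5Event("chr1", 10), Tn5Event("chr1", 19), Tn5Event("chr1", 20)]
        kept = filter_blacklisted(events, bl)
        assert [ev.pos for ev in kept] == [9, 20]


class TestTsv:
    def test_round_trip_preserves_event_multiset(self, tmp_path, rng):
        events = [
            Tn5Event("chr1", int(p), "+" if rng.random() < 0.5 else "-",
                     f"BC{int(b)}" if b >= 0 else None)
            for p, b in zip(rng.integers(0, 1000, 200), rng.integers(-1, 5, 200))
        ]
        path = tmp_path / "events.tsv"
        write_events_tsv(events, path)
        back = read_tn5_events(str(path), mode="dnase")
        assert collections.Counter(back) == collections.Counter(events)

    def test_barcodes_preserved(self, tmp_path):
        path = tmp_path / "frag.tsv"
        path.write_text("chr1\t5\t200\tCELL42\n")
        (ev,) = read_tn5_events(str(path))
        assert ev.barcode == "CELL42" and ev.pos == 5

    def test_both_ends_mode_adds_end_insertion(self, tmp_path):
        path = tmp_path / "frag.tsv"
        path.write_text("chr1\t5\t200\tCELL42\n")
        events = read_tn5_events(str(path), fragment_ends="both")
        assert sorted(ev.pos for ev in events) == [5, 199]

    def test_count_column_repeats_event(self, tmp_path):
        path = tmp_path / "frag.tsv"
        path.write_text("chr1\t5\t6\tCELL1\t3\n")
        events = read_tn5_events(str(path))
        assert len(events) == 3

    def test_malformed_line_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chr1\t5\n")
        with pytest.raises(InputFormatError):
            read_tn5_events(str(path))


class TestCountTrack:
    def test_direct_tally(self):
        events = [Tn5Event("chr1", 5), Tn5Event("chr1", 5), Tn5Event("chr1", 7)]
        track = build_count_track(events, "chr1", 10)
        assert track.counts.tolist() == [0, 0, 0, 0, 0, 2, 0, 1, 0, 0]
        assert track.counts.sum() == len(events)

    def test_empty_event_list_gives_zero_track(self):
        track = build_count_track([], "chr1", 5)
        assert track.counts.tolist() == [0] * 5

    def test_barcodes_pooled_per_base(self):
        events = [Tn5Event("chr1", 3, "+", "A"), Tn5Event("chr1", 3, "+", "B")]
        track = build_count_track(events, "chr1", 5)
        assert track.counts[3] == 2

    def test_out_of_bounds_event_named_in_error(self):
        with pytest.raises(OutOfBoundsError, match="chr1"):
            build_count_track([Tn5Event("chr1", 12)], "chr1", 10)


class TestSegmentBatches:
    def test_long_zero_run_splits(self):
        counts = np.concatenate([[1, 1], np.zeros(5000, np.int64), [2, 2]])
        batches = segment_batches(CountTrack("chr1", 0, counts), min_gap=5000)
        assert len(batches) == 2
        assert batches[0].counts.counts.tolist() == [1, 1]
        assert batches[1].counts.counts.tolist() == [2, 2]
        assert batches[1].interval.start == 5002

    def test_all_zero_track_gives_no_batches(self):
        assert segment_batches(CountTrack("chr1", 0, np.zeros(100, np.int64))) == []

    def test_short_gaps_keep_single_batch(self):
        counts = np.concatenate([[1], np.zeros(10, np.int64), [1]])
        batches = segment_batches(CountTrack("chr1", 0, counts), min_gap=50)
        assert len(batches) == 1
        assert len(batches[0].counts) == 12

    @given(
        counts=st.lists(st.integers(0, 3), min_size=1, max_size=200),
        min_gap=st.integers(1, 20),
    )
    @settings(max_examples=80, deadline=None)
    def test_reconstruction_and_coverage(self, counts, min_gap):
        track = CountTrack("chr1", 0, np.array(counts, dtype=np.int64))
        batches = segment_batches(track, min_gap)
        # Every nonzero base lies inside a batch, gaps between/around
        # batches are all-zero runs of >= min_gap (except short track ends).
        covered = np.zeros(len(counts), dtype=bool)
        for b in batches:
            covered[b.interval.start : b.interval.end] = True
            np.testing.assert_array_equal(
                b.counts.counts, track.counts[b.interval.start : b.interval.end]
            )
        assert not (np.array(counts) > 0)[~covered].any()
        # gaps between consecutive batches are >= min_gap and zero
        for a, b in zip(batches, batches[1:]):
            gap = track.counts[a.interval.end : b.interval.start]
            assert len(gap) >= min_gap and not gap.any()

    def test_invariant_to_split_and_remerge_at_zero_base(self, rng):
        counts = rng.integers(0, 3, 400)
        counts[100:140] = 0
        track = CountTrack("chr1", 0, counts)
        ref = [(b.interval.start, b.interval.end) for b in segment_batches(track, 20)]
        # split at a zero base inside the long zero run, re-merge
        left, right = counts[:120], counts[120:]
        merged = CountTrack("chr1", 0, np.concatenate([left, right]))
        again = [(b.interval.start, b.interval.end) for b in segment_batches(merged, 20)]
        assert ref == again
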