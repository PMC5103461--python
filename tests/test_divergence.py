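"""Sliding-window divergence: aligner recovery, call-track rules,
window/summary conservation, smoothing properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import straindiverge as sd
from straindiverge.divergence import (
    CallTrack,
    align_assemblies,
    anchor_align,
    build_call_track,
    smooth,
    summarize,
    window_stats,
)


def _assembly(seq, name="s1"):
    return sd.GenomeAssembly([sd.SequenceRecord(id=name, residues=seq)])


class TestAnchorAlign:
    def test_identical_sequences_single_clean_block(self, rng):
        s = "".join(rng.choice(list("ACGT"), 10_000))
        rec = sd.SequenceRecord(id="s", residues=s)
        blocks = anchor_align(rec, rec)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.ref_text == b.query_text == s

    def test_blocks_reproduce_sources(self, small_pair):
        anc, der, _ = small_pair
        blocks = align_assemblies(anc, der)
        for b in blocks:
            ref_sub = b.ref_text.replace("-", "")
            n = len(ref_sub)
            assert anc[b.ref_id].residues[b.ref_start:b.ref_start + n] == ref_sub
            qry_sub = b.query_text.replace("-", "")
            m = len(qry_sub)
            assert der[b.query_id].residues[b.query_start:b.query_start + m] == qry_sub

    def test_coverage_and_exact_mismatch_recovery(self, small_pair):
        # indel-free pair: blocks cover >= 99% of sites and the column
        # mismatch fraction equals the planted fraction exactly on them
        anc, der, truth = small_pair
        track = build_call_track({"q": align_assemblies(anc, der)}, anc)
        called = track.called_mask("scaffold_1", query="q", joint=False)
        assert called.mean() >= 0.99
        mism = track.mismatch_mask("scaffold_1", "q")
        subs = truth.scaffolds["scaffold_1"].substitutions
        planted_called = np.zeros(len(called), bool)
        planted_called[subs] = True
        assert int(mism.sum()) == int((planted_called & called).sum())

    def test_insertion_bridged_between_anchors(self):
        rng = np.random.default_rng(13)
        left = "".join(rng.choice(list("ACGT"), 3000))
        right = "".join(rng.choice(list("ACGT"), 3000))
        ins = "".join(rng.choice(list("ACGT"), 500))
        ref = sd.SequenceRecord(id="r", residues=left + right)
        qry = sd.SequenceRecord(id="q", residues=left + ins + right)
        blocks = anchor_align(ref, qry)
        assert len(blocks) == 1
        gap_run = blocks[0].ref_text.count("-")
        assert gap_run == 500

    def test_no_anchors_gives_empty_list(self):
        r = sd.SequenceRecord(id="r", residues="A" * 200)
        q = sd.SequenceRecord(id="q", residues="C" * 200)
        assert anchor_align(r, q) == []


class TestCallTrack:
    def _toy_track(self):
        # 30-bp reference; one block with 2 planted mismatch columns
        ref = "ACGTACGTACGTACGTACGTACGTACGTAC"
        qry = ref[:5] + "G" + ref[6:20] + "T" + ref[21:]  # mismatch at 5 and 20
        asm = _assembly(ref)
        block = sd.AlignmentBlock(ref_id="s1", ref_start=0, query_id="q",
                                  query_start=0, strand="+",
                                  ref_text=ref, query_text=qry)
        return asm, block

    def test_hand_counted_mismatches(self):
        asm, block = self._toy_track()
        track = build_call_track({"q": [block]}, asm)
        mism = track.mismatch_mask("s1", "q")
        assert sorted(np.nonzero(mism)[0].tolist()) == [5, 20]

    def test_n_run_positions_uncalled(self):
        ref = "ACGT" * 10
        qry = "ACGT" * 3 + "NNNN" + "ACGT" * 6
        asm = _assembly(ref)
        block = sd.AlignmentBlock(ref_id="s1", ref_start=0, query_id="q",
                                  query_start=0, strand="+",
                                  ref_text=ref, query_text=qry)
        track = build_call_track({"q": [block]}, asm)
        called = track.called_mask("s1", query="q", joint=False)
        assert not called[12:16].any()
        assert called[:12].all() and called[16:].all()

    def test_multiply_covered_positions_uncalled(self):
        asm, block = self._toy_track()
        track = build_call_track({"q": [block, block]}, asm)
        called = track.called_mask("s1", query="q", joint=False)
        assert not called.any()
        assert track.n_overlap_uncalled == 30

    def test_gap_columns_uncalled(self):
        ref = "AAAACCCCGGGG"
        asm = _assembly(ref)
        block = sd.AlignmentBlock(ref_id="s1", ref_start=0, query_id="q",
                                  query_start=0, strand="+",
                                  ref_text=ref, query_text="AAAA----GGGG")
        track = build_call_track({"q": [block]}, asm)
        called = track.called_mask("s1", query="q", joint=False)
        assert not called[4:8].any() and called[:4].all() and called[8:].all()


class TestWindowStats:
    def _track_from_masks(self, n, called_idx, mism_idx):
        asm = _assembly("A" * n)
        track = CallTrack(asm, ["q"])
        st_arr = track.states["q"]["s1"]
        st_arr[called_idx] = 1
        st_arr[mism_idx] = 2
        return track

    def test_min_called_boundary(self):
        # 499 called -> discarded; 500 -> retained
        t499 = self._track_from_masks(1000, np.arange(499), [])
        t500 = self._track_from_masks(1000, np.arange(500), [])
        assert window_stats(t499)[0].retained is False
        assert window_stats(t500)[0].retained is True

    def test_hand_counted_window_values(self):
        # 3-kb toy, 30 mismatches planted in window 2 only
        called = np.arange(3000)
        mism = np.arange(1000, 1030)
        track = self._track_from_masks(3000, called, mism)
        ws = window_stats(track)
        assert [w.value for w in ws] == [0.0, 0.03, 0.0]

    def test_conservation_against_track_totals(self, small_pair):
        anc, der, _ = small_pair
        track = build_call_track({"q": align_assemblies(anc, der)}, anc)
        ws = window_stats(track, query="q", min_called=0)
        called = track.called_mask("scaffold_1", query="q", joint=False)
        mism = track.mismatch_mask("scaffold_1", "q") & called
        assert sum(w.called for w in ws) == int(called.sum())
        assert sum(w.mismatches for w in ws) == int(mism.sum())

    def test_block_order_invariance(self, small_pair):
        anc, der, _ = small_pair
        blocks = align_assemblies(anc, der)
        a = window_stats(build_call_track({"q": blocks}, anc), query="q")
        b = window_stats(build_call_track({"q": blocks[::-1]}, anc), query="q")
        assert [(w.called, w.mismatches) for w in a] == \
               [(w.called, w.mismatches) for w in b]

    def test_bad_window_rejected(self):
        track = self._track_from_masks(100, [], [])
        with pytest.raises(ValueError):
            window_stats(track, window=0)


class TestSmooth:
    def _stats(self, values, retained=None):
        retained = retained or [True] * len(values)
        return [sd.WindowStat(scaffold="s", start=1000 * i, called=1000,
                              mismatches=int(1000 * v), value=v, retained=r)
                for i, (v, r) in enumerate(zip(values, retained))]

    def test_constant_track_is_fixed_point(self):
        pts = smooth(self._stats([0.04] * 20))
        assert all(p.value == pytest.approx(0.04) for p in pts)

    def test_isolated_window_keeps_raw_value(self):
        stats = self._stats([0.1, 0.5, 0.1], retained=[False, True, False])
        pts = smooth(stats)
        assert len(pts) == 1
        assert pts[0].value == pytest.approx(0.5)

    def test_eleven_window_mean(self):
        values = [i / 100 for i in range(11)]   # 0.00 .. 0.10
        pts = smooth(self._stats(values))
        assert pts[5].value == pytest.approx(0.05)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_contraction(self, values):
        pts = smooth(self._stats(values))
        lo, hi = min(values), max(values)
        assert all(lo - 1e-12 <= p.value <= hi + 1e-12 for p in pts)

    def test_no_points_for_discarded_windows(self):
        pts = smooth(self._stats([0.1, 0.2], retained=[False, False]))
        assert pts == []


class TestSummarize:
    def test_identical_pair_zero(self, rng):
        s = "".join(rng.choice(list("ACGT"), 30_000))
        asm = _assembly(s)
        track = build_call_track(
            {"q": [sd.AlignmentBlock(ref_id="s1", ref_start=0, query_id="q",
                                     query_start=0, strand="+",
                                     ref_text=s, query_text=s)]}, asm)
        summary = summarize(window_stats(track))
        assert summary["genome"]["divergence"] == 0.0

    def test_zero_retained_flagged_not_zero(self):
        stats = [sd.WindowStat(scaffold="s", start=0, called=10, mismatches=0,
                               value=0.0, retained=False)]
        assert summarize(stats)["genome"]["divergence"] is None

    def test_micro_average_pools_counts(self):
        stats = [
            sd.WindowStat("s", 0, called=1000, mismatches=100, value=0.1,
                          retained=True),
            sd.WindowStat("s", 1000, called=500, mismatches=0, value=0.0,
                          retained=True),
        ]
        s = summarize(stats)
        assert s["genome"]["divergence"] == pytest.approx(100 / 1500)
        assert s["per_scaffold"]["s"]["divergence"] == pytest.approx(100 / 1500)


class TestThreeWayMode:
    def test_joint_calledness_requires_both_queries(self):
        ref = "ACGT" * 25
        asm = _assembly(ref)
        full = sd.AlignmentBlock(ref_id="s1", ref_start=0, query_id="q1",
                                 query_start=0, strand="+",
                                 ref_text=ref, query_text=ref)
        half = sd.AlignmentBlock(ref_id="s1", ref_start=0, query_id="q2",
                                 query_start=0, strand="+",
                                 ref_text=ref[:48], query_text=ref[:48])
        track = build_call_track({"q1": [full], "q2": [half]}, asm)
        joint = track.called_mask("s1", joint=True)
        assert joint[:48].all() and not joint[48:].any()
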