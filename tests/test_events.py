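"""Tract segmentation, event classification, complex merging, junctions."""
import numpy as np
import pytest

from lohscan.events import (
    annotate_junctions, breakpoint_position, classify, merge_complex, segment,
)
from lohscan.model import EventCall
from conftest import make_binned_track


def call_states(genome, states, min_snps=5, merge=True, **kw):
    track = make_binned_track(genome, states)
    events = classify(segment(track), genome, isolate_id="iso", min_snps=min_snps, **kw)
    if merge:
        events = merge_complex(events, genome)
    return events


class TestSegment:
    def test_three_tracts(self, toy_genome):
        states = {"chrA": [(1, 1)] * 10 + [(2, 0)] * 5 + [(1, 1)] * 85}
        tracts = [t for t in segment(make_binned_track(toy_genome, states))
                  if t.chromosome == "chrA"]
        assert [t.state for t in tracts] == [(1, 1), (2, 0), (1, 1)]
        assert [t.n_snps for t in tracts] == [10, 5, 85]

    def test_all_het_single_tract(self, toy_genome):
        tracts = segment(make_binned_track(toy_genome, {}))
        assert len(tracts) == 2  # one per chromosome
        assert all(t.state == (1, 1) for t in tracts)

    def test_masked_snps_do_not_break_runs(self, toy_genome):
        track = make_binned_track(toy_genome, {})
        track.data.loc[20, "masked"] = True
        tracts = [t for t in segment(track) if t.chromosome == "chrA"]
        assert len(tracts) == 1
        assert tracts[0].n_snps == 99


class TestClassify:
    def test_whole_chromosome_copy_neutral_is_upd(self, toy_genome):
        ev = call_states(toy_genome, {"chrB": [(2, 0)] * 60})
        assert [e.event_class for e in ev] == ["UPD"]
        assert ev[0].retained_parent == "P1"

    def test_terminal_loh_retaining_p2(self, toy_genome):
        states = {"chrA": [(1, 1)] * 50 + [(0, 2)] * 50}
        (e,) = call_states(toy_genome, states)
        assert e.event_class == "T_LOH"
        assert e.retained_parent == "P2"
        assert e.bp_right is None
        assert e.bp_left == (49_500, 50_500)
        assert e.n_transitions == 1 and not e.is_complex

    def test_small_interior_deletion_not_large(self, toy_genome):
        # 4 kb < the 5 kb threshold for "large" deletions/duplications
        states = {"chrA": [(1, 1)] * 40 + [(1, 0)] * 5 + [(1, 1)] * 55}
        (e,) = call_states(toy_genome, states)
        assert e.event_class == "I_DEL" and not e.large
        assert e.size == 4001

    def test_large_duplication_flagged(self, toy_genome):
        states = {"chrA": [(1, 1)] * 30 + [(2, 1)] * 20 + [(1, 1)] * 50}
        (e,) = call_states(toy_genome, states)
        assert e.event_class == "I_DUP" and e.large

    def test_unmapped_state_surfaced_as_other(self, toy_genome):
        states = {"chrA": [(1, 1)] * 40 + [(3, 1)] * 8 + [(1, 1)] * 52}
        ev = call_states(toy_genome, states)
        assert [e.event_class for e in ev] == ["OTHER"]

    def test_monosomy_trisomy_tetrasomy(self, toy_genome):
        for state, cls in [((1, 0), "MONOSOMY"), ((1, 2), "TRISOMY"),
                           ((2, 2), "TETRASOMY")]:
            ev = call_states(toy_genome, {"chrB": [state] * 60})
            assert [e.event_class for e in ev] == [cls]

    def test_sub_threshold_tracts_ignored(self, toy_genome):
        states = {"chrA": [(1, 1)] * 40 + [(2, 0)] * 4 + [(1, 1)] * 56}
        assert call_states(toy_genome, states, min_snps=5) == []

    def test_noise_fragment_keeps_whole_chromosome_identity(self, toy_genome):
        # a short unclassifiable excursion inside a UPD chromosome
        states = {"chrB": [(2, 0)] * 30 + [(3, 0)] * 3 + [(2, 0)] * 27}
        ev = call_states(toy_genome, states)
        assert [e.event_class for e in ev] == ["UPD"]

    def test_reversed_marker_order_swaps_terminal_side_only(self, toy_genome):
        states = {"chrA": [(0, 2)] * 30 + [(1, 1)] * 70}
        (fwd,) = call_states(toy_genome, states)
        states_r = {"chrA": list(reversed(states["chrA"]))}
        (rev,) = call_states(toy_genome, states_r)
        assert fwd.event_class == rev.event_class == "T_LOH"
        assert fwd.bp_left is None and rev.bp_right is None
        assert fwd.n_snps == rev.n_snps


class TestMergeComplex:
    def test_alternating_tracts_merge_to_one_complex_event(self, toy_genome):
        # LOH | short het gap | opposite LOH -> one event, 4 transitions
        states = {"chrA": [(1, 1)] * 20 + [(2, 0)] * 20 + [(1, 1)] * 3
                  + [(0, 2)] * 20 + [(1, 1)] * 37}
        ev = call_states(toy_genome, states)
        assert len(ev) == 1
        e = ev[0]
        assert e.event_class == "I_LOH" and e.is_complex
        assert e.n_transitions == 4

    def test_distant_events_stay_separate(self, toy_genome):
        # 40 kb of baseline (40 markers) between two LOH tracts
        states = {"chrA": [(1, 1)] * 10 + [(2, 0)] * 10 + [(1, 1)] * 40
                  + [(2, 0)] * 10 + [(1, 1)] * 30}
        ev = call_states(toy_genome, states)
        assert len(ev) == 2
        assert all(not e.is_complex for e in ev)

    def test_clean_terminal_loh_single_transition(self, toy_genome):
        states = {"chrA": [(1, 1)] * 60 + [(2, 0)] * 40}
        (e,) = call_states(toy_genome, states)
        assert e.n_transitions == 1 and not e.is_complex

    def test_merged_event_reaching_both_ends_promoted(self, toy_genome):
        # terminal LOH on both sides separated by a short het gap: UPD-like
        states = {"chrB": [(2, 0)] * 28 + [(1, 1)] * 4 + [(2, 0)] * 28}
        ev = call_states(toy_genome, states)
        assert [e.event_class for e in ev] == ["UPD"]
        assert ev[0].is_complex


class TestJunctions:
    def test_interstitial_deletion_between_repeat_pair(self, toy_genome):
        # deletion spanning exactly the interval between the chrA Ty1 pair
        pos = toy_genome.snp_positions("chrA")
        inside = (pos >= 21_000) & (pos <= 61_000)
        states = {"chrA": [(1, 0) if m else (1, 1) for m in inside]}
        ev = call_states(toy_genome, states)
        ev, cands = annotate_junctions(ev, toy_genome)
        assert ev[0].event_class == "I_DEL"
        assert ev[0].junction_repeat_family == "Ty1"
        assert cands == []

    def test_translocation_pairing_same_family(self, toy_genome):
        # T_DEL distal to the chrA repeat + T_DUP distal to the chrB repeat
        posA = toy_genome.snp_positions("chrA")
        posB = toy_genome.snp_positions("chrB")
        states = {
            "chrA": [(1, 0) if p >= 61_000 else (1, 1) for p in posA],
            "chrB": [(2, 1) if p >= 41_000 else (1, 1) for p in posB],
        }
        ev = call_states(toy_genome, states)
        ev, cands = annotate_junctions(ev, toy_genome)
        assert len(cands) == 1
        assert cands[0].repeat_family == "Ty1"
        assert cands[0].del_event.chromosome == "chrA"
        assert cands[0].dup_event.chromosome == "chrB"

    def test_deletion_without_repeats_left_unannotated(self, toy_genome):
        states = {"chrB": [(1, 1)] * 10 + [(0, 1)] * 10 + [(1, 1)] * 40}
        ev = call_states(toy_genome, states)
        ev, _ = annotate_junctions(ev, toy_genome)
        assert ev[0].junction_repeat_family is None


class TestBreakpointPosition:
    def test_midpoint_floored(self):
        e = EventCall("i", "I_LOH", "chrA", 12_000, 20_000,
                      bp_left=(10_000, 12_000), bp_right=(20_000, 21_001))
        assert breakpoint_position(e) == [11_000, 20_500]

    def test_terminal_event_single_midpoint(self):
        e = EventCall("i", "T_LOH", "chrA", 50_000, 99_500,
                      bp_left=(49_000, 50_000))
        assert breakpoint_position(e) == [49_500]

    def test_degenerate_interval(self):
        e = EventCall("i", "I_LOH", "chrA", 5, 10, bp_left=(5, 5),
                      bp_right=(10, 12))
        assert breakpoint_position(e)[0] == 5
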