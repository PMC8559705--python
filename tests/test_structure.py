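import numpy as np
import pytest

from rdnarray.seqio import Read
from rdnarray.splitmap import ReadAlignmentMap, SplitAlignment, map_splits, split_read
from rdnarray.structure import (InvertedReadError, InversionCall,
                                classify_palindrome,
                                cluster_inversion_breakpoints,
                                detect_inversion, detect_quality_drop,
                                detect_structural_gaps, locate_inversion_point,
                                segment_copies, summarize_noncanonical)
from rdnarray.simdata import (ERROR_FREE, ArraySpec, CopySpec, ErrorModel,
                              simulate_array_read, simulate_template_switch)


def synthetic_map(strands, read_length=None, split=300):
    """Hand-built alignment map with the given per-section strands."""
    splits = [SplitAlignment(i * split, split, i * split % 40_000, s)
              for i, s in enumerate(strands)]
    n = len(strands) * split
    amap = ReadAlignmentMap("synthetic", read_length or n, split, splits)
    n_fwd = sum(1 for s in strands if s == "+")
    amap.dominant_strand = "+" if n_fwd >= len(strands) - n_fwd else "-"
    amap.dominant_fraction = max(n_fwd, len(strands) - n_fwd) / len(strands)
    return amap


class TestSegmentCopies:
    def test_two_exact_units_from_origin(self, ref, aligner):
        read = Read("r", ref.unit_sequence * 2)
        amap = map_splits(split_read(read), ref, aligner)
        segs = segment_copies(amap, ref)
        complete = [s for s in segs if s.complete]
        assert len(complete) == 2
        assert complete[0].coding_read_interval is not None

    def test_subunit_read_has_no_complete_segment(self, ref, aligner):
        read = Read("r", ref.unit_sequence[3_000: 30_000])
        amap = map_splits(split_read(read), ref, aligner)
        assert sum(s.complete for s in segment_copies(amap, ref)) == 0

    def test_mid_igs_multi_unit_read_matches_truth(self, ref, aligner):
        # ~2.6 units starting mid-IGS: truth says which copies are complete
        spec = ArraySpec(copies=[CopySpec(3, 2)] * 3)
        read, truth = simulate_array_read(ref, spec, start_phase=17_000,
                                          errors=ERROR_FREE, seed=1)
        amap = map_splits(split_read(read), ref, aligner)
        segs = segment_copies(amap, ref)
        assert sum(s.complete for s in segs) == truth.n_complete_copies
        assert len(segs) == len(truth.copies)

    def test_inverted_read_rejected(self, ref):
        amap = synthetic_map(["+"] * 5 + ["-"] * 5)
        with pytest.raises(InvertedReadError):
            segment_copies(amap, ref)


class TestStructuralGaps:
    def test_error_free_read_clean(self, ref, aligner):
        read, _ = simulate_array_read(ref, ArraySpec(copies=[CopySpec(3, 2)] * 2),
                                      errors=ERROR_FREE, seed=2)
        amap = map_splits(split_read(read), ref, aligner)
        assert detect_structural_gaps(amap, ref) == []

    def test_planted_coding_deletion_detected(self, ref, aligner):
        spec = ArraySpec(copies=[CopySpec(3, 2, [("deletion", 2_000, 5_000)]),
                                 CopySpec(3, 2)])
        read, _ = simulate_array_read(ref, spec, errors=ERROR_FREE, seed=3)
        amap = map_splits(split_read(read), ref, aligner)
        events = [e for e in detect_structural_gaps(amap, ref)
                  if not e.suppressed]
        assert len(events) == 1
        assert events[0].event_class == "deletion"
        assert abs(events[0].deviation - 5_000) <= 300

    def test_satellite_expansion_suppressed(self, ref, aligner):
        # one extra ~680-bp R unit: a >500-nt deviation, but both flanks lie
        # in the R-repeat region, so the event must be suppressed
        spec = ArraySpec(copies=[CopySpec(4, 2), CopySpec(3, 2)])
        read, _ = simulate_array_read(ref, spec, errors=ERROR_FREE, seed=4)
        amap = map_splits(split_read(read), ref, aligner)
        events = detect_structural_gaps(amap, ref)
        assert events, "expansion should produce a gap event"
        assert all(e.suppressed for e in events)

    def test_threshold_is_strict(self, ref):
        # deviation of exactly the threshold is not an event
        splits = [SplitAlignment(0, 300, 1_000, "+"),
                  SplitAlignment(300, 300, 1_800, "+")]
        amap = ReadAlignmentMap("r", 600, 300, splits)
        assert detect_structural_gaps(amap, ref, threshold=500) == []
        splits[1] = SplitAlignment(300, 300, 1_801, "+")
        amap = ReadAlignmentMap("r", 600, 300, splits)
        assert len(detect_structural_gaps(amap, ref, threshold=500)) == 1


class TestInversionDetection:
    def test_fully_forward_read_not_inverted(self):
        assert detect_inversion(synthetic_map(["+"] * 100)) is None

    def test_fifteen_percent_opposite_is_inverted(self):
        call = detect_inversion(synthetic_map(["+"] * 85 + ["-"] * 15))
        assert call is not None

    def test_exactly_ten_percent_is_not_inverted(self):
        assert detect_inversion(synthetic_map(["+"] * 90 + ["-"] * 10)) is None

    def test_locate_point_midpoint(self):
        amap = synthetic_map(["+"] * 50 + ["-"] * 50)
        call = locate_inversion_point(amap)
        assert call.read_offset == 50 * 300
        assert call.relative_position == pytest.approx(0.5)
        assert not call.complex

    def test_forward_only_read_raises(self):
        with pytest.raises(ValueError, match="transition"):
            locate_inversion_point(synthetic_map(["+"] * 20))

    def test_multiple_transitions_flagged_complex(self):
        amap = synthetic_map(["+"] * 20 + ["-"] * 20 + ["+"] * 20)
        assert locate_inversion_point(amap).complex

    def test_template_switch_relative_position(self, ref, aligner):
        # fully sequenced second strand folds the read at its centre
        base, _ = simulate_array_read(ref, ArraySpec(copies=[CopySpec(3, 2)]),
                                      start_phase=12_000, errors=ERROR_FREE,
                                      seed=5)
        art, truth = simulate_template_switch(base, termination=1.0, seed=5)
        amap = map_splits(split_read(art), ref, aligner)
        call = detect_inversion(amap)
        assert call is not None
        assert call.relative_position == pytest.approx(0.5, abs=0.01)
        # second strand terminated at 25% of the first strand's length
        art, _ = simulate_template_switch(base, termination=0.25, seed=5)
        amap = map_splits(split_read(art), ref, aligner)
        call = detect_inversion(amap)
        assert call.relative_position == pytest.approx(0.8, abs=0.01)


class TestQualityDrop:
    def test_flat_profile_no_drop(self):
        assert detect_quality_drop(np.full(20_000, 12), 8_000) is False

    def test_step_drop_detected(self):
        q = np.concatenate([np.full(10_000, 14), np.full(10_000, 7)])
        assert detect_quality_drop(q, 10_000) is True

    def test_small_step_below_threshold(self):
        q = np.concatenate([np.full(10_000, 14), np.full(10_000, 11)])
        assert detect_quality_drop(q, 10_000) is False

    def test_inversion_near_read_end_undetermined(self):
        assert detect_quality_drop(np.full(10_000, 12), 9_500) is None


class TestPalindromeClassification:
    @pytest.mark.parametrize("relative,drop,expected", [
        (0.75, False, "artifact_consistent"),
        (0.5, False, "artifact_consistent"),
        (0.3, False, "candidate_real"),
        (0.3, True, "dubious"),
    ])
    def test_rule(self, relative, drop, expected):
        call = InversionCall("r", int(relative * 10_000), relative, 0.4,
                             1_000, ("+", "-"), quality_drop=drop)
        assert classify_palindrome(call) == expected


class TestBreakpointClustering:
    def call_at(self, ref_pos, orientation=("+", "-"), rid="r"):
        return InversionCall(rid, 0, 0.5, 0.4, ref_pos, orientation)

    def test_nearby_same_orientation_recurrent(self, ref):
        groups = cluster_inversion_breakpoints(
            [self.call_at(5_000, rid="a"), self.call_at(5_200, rid="b")], ref)
        assert len(groups) == 1
        assert groups[0]["recurrent"] and groups[0]["size"] == 2

    def test_singleton_not_recurrent(self, ref):
        groups = cluster_inversion_breakpoints([self.call_at(5_000)], ref)
        assert len(groups) == 1 and not groups[0]["recurrent"]

    def test_different_orientation_not_linked(self, ref):
        groups = cluster_inversion_breakpoints(
            [self.call_at(5_000, ("+", "-")), self.call_at(5_100, ("-", "+"))],
            ref)
        assert all(not g["recurrent"] for g in groups)

    def test_empty_input(self, ref):
        assert cluster_inversion_breakpoints([], ref) == []


class TestSummary:
    def test_rates_from_truth_bookkeeping(self):
        records = ([{"n_complete_copies": 10, "n_unsuppressed_events": 1,
                     "palindrome_class": None}] * 3 +
                   [{"n_complete_copies": 10, "n_unsuppressed_events": 0,
                     "palindrome_class": None}] * 97)
        s = summarize_noncanonical(records)
        assert s["total_copies"] == 1_000
        assert s["noncanonical_rate_per_copy"] == pytest.approx(0.003)
        assert s["candidate_real_rate_per_copy"] == 0.0

    def test_zero_copies_undefined(self):
        s = summarize_noncanonical([])
        assert s["noncanonical_rate_per_copy"] is None

    def test_artifact_only_palindromes_zero_candidate_rate(self):
        records = [{"n_complete_copies": 5, "n_unsuppressed_events": 0,
                    "palindrome_class": "artifact_consistent"}] * 10
        s = summarize_noncanonical(records)
        assert s["candidate_real_rate_per_copy"] == 0.0
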