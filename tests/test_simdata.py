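import numpy as np
import pytest

from rdnarray.kmeralign import revcomp
from rdnarray.methylation import DEFAULT_METHYL_BORDER
from rdnarray.simdata import (ERROR_FREE, ArraySpec, CopySpec, ErrorModel,
                              SampleScenario, apply_errors,
                              make_synthetic_reference,
                              markov_methylation_states, simulate_array_read,
                              simulate_methylation_calls, simulate_sample,
                              simulate_template_switch,
                              simulate_true_palindrome)


class TestSyntheticReference:
    def test_unit_length_arithmetic(self):
        r = make_synthetic_reference(n_r=3, n_bl=2, backbone_length=30_000,
                                     seed=0)
        assert r.unit_length == 30_000 + 3 * 680 + 2 * 4_500 == 41_040

    def test_fixed_seed_reproducible(self):
        a = make_synthetic_reference(seed=5)
        b = make_synthetic_reference(seed=5)
        assert a.unit_sequence == b.unit_sequence
        assert a.unit_sequence != make_synthetic_reference(seed=6).unit_sequence

    def test_zero_r_units_gives_empty_interval(self):
        r = make_synthetic_reference(n_r=0, seed=0)
        lo, hi = r.r_repeat_interval
        assert lo == hi

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_reference(n_r=-1)

    def test_satellite_units_are_divergent_copies(self):
        r = make_synthetic_reference(seed=0)
        u0, u1 = r.parts["r_units"][:2]
        mismatches = sum(a != b for a, b in zip(u0, u1))
        assert 0 < mismatches / len(u0) < 0.3


class TestApplyErrors:
    def test_zero_rates_identity(self):
        seq = "ACGT" * 100
        out, cum = apply_errors(seq, ERROR_FREE, np.random.default_rng(0))
        assert out == seq
        assert cum[-1] == len(seq)

    def test_realized_rates_near_nominal(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200_000))
        em = ErrorModel(0.03, 0.01, 0.01)
        out, cum = apply_errors(seq, em, rng)
        # net length change = insertions - deletions (each 1%)
        assert abs(len(out) - len(seq)) < 0.005 * len(seq)
        assert np.all(np.diff(cum) >= 0)  # coordinate map is monotone

    def test_coordinate_map_tracks_positions(self):
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000))
        out, cum = apply_errors(seq, ErrorModel(0.0, 0.05, 0.0), rng)
        # pure insertion: every clean position maps at or beyond itself
        assert np.all(cum[:-1] >= np.arange(len(seq)))
        assert cum[-1] == len(out)


class TestArrayReads:
    def test_two_unmodified_units_exact_length(self, ref):
        spec = ArraySpec(copies=[CopySpec(3, 2)] * 2)
        read, truth = simulate_array_read(ref, spec, errors=ERROR_FREE, seed=0)
        assert len(read) == 2 * ref.unit_length
        assert truth.n_complete_copies == 2

    def test_fixed_seed_identical_read(self, ref):
        spec = ArraySpec(copies=[CopySpec(3, 2)] * 2)
        a, _ = simulate_array_read(ref, spec, errors=ErrorModel(), seed=9)
        b, _ = simulate_array_read(ref, spec, errors=ErrorModel(), seed=9)
        assert a.sequence == b.sequence
        assert np.array_equal(a.qualities, b.qualities)

    def test_truth_deltas_reflect_copy_spec(self, ref):
        spec = ArraySpec(copies=[CopySpec(4, 1)])
        _, truth = simulate_array_read(ref, spec, errors=ERROR_FREE, seed=0)
        assert truth.copies[0]["delta_r"] == 680
        assert truth.copies[0]["delta_bl"] == -4_500

    def test_oversized_event_rejected(self, ref):
        spec = ArraySpec(copies=[CopySpec(3, 2, [("deletion", 0, 50_000)])])
        with pytest.raises(ValueError):
            simulate_array_read(ref, spec, errors=ERROR_FREE, seed=0)


class TestTemplateSwitch:
    def base_read(self, ref, seed=0):
        read, _ = simulate_array_read(ref, ArraySpec(copies=[CopySpec(3, 2)]),
                                      errors=ERROR_FREE, seed=seed)
        return read

    def test_complete_second_strand_centres_inversion(self, ref):
        read = self.base_read(ref)
        art, truth = simulate_template_switch(read, termination=1.0)
        assert truth.inversion_offset / len(art) == pytest.approx(0.5, abs=1e-3)
        # the appended part is the reverse complement of the first strand
        assert art.sequence[len(read):] == revcomp(read.sequence)

    @pytest.mark.parametrize("f", [0.1, 0.4, 0.7, 1.0])
    def test_relative_position_at_least_half(self, ref, f):
        art, truth = simulate_template_switch(self.base_read(ref), f)
        assert truth.inversion_offset / len(art) >= 0.5

    def test_second_strand_quality_reduced(self, ref):
        read = self.base_read(ref)
        art, truth = simulate_template_switch(read, 0.5, quality_drop=7)
        q1 = art.qualities[: truth.inversion_offset].mean()
        q2 = art.qualities[truth.inversion_offset:].mean()
        assert q1 - q2 == pytest.approx(7, abs=0.5)

    def test_deterministic_under_seed(self, ref):
        read = self.base_read(ref)
        a, _ = simulate_template_switch(read, "uniform", seed=4)
        b, _ = simulate_template_switch(read, "uniform", seed=4)
        assert a.sequence == b.sequence

    def test_invalid_termination_rejected(self, ref):
        with pytest.raises(ValueError):
            simulate_template_switch(self.base_read(ref), 0.0)


class TestTruePalindrome:
    def test_framing_spreads_inversion_position(self, ref):
        rels = []
        for seed in range(12):
            read, truth = simulate_true_palindrome(ref, seed=seed)
            rels.append(truth.inversion_offset / len(read))
        assert min(rels) < 0.5 < max(rels)


class TestMethylationCalls:
    def run_copy(self, ref, state, seed):
        spec = ArraySpec(copies=[CopySpec(3, 2, meth_state=state)] * 3)
        _, truth = simulate_array_read(ref, spec, start_phase=20_000,
                                       errors=ERROR_FREE, seed=0)
        calls = simulate_methylation_calls(truth, seed=seed)
        a, b = truth.copies[1]["read_coding_interval"]
        inside = [c.posterior for c in calls if a <= c.position < b]
        return float(np.mean(inside)), len(inside)

    def test_bimodal_states_separate_at_border(self, ref):
        hits = 0
        for seed in range(20):
            mean_u, n = self.run_copy(ref, "U", seed)
            mean_m, _ = self.run_copy(ref, "M", seed + 100)
            assert n >= 50
            hits += (mean_u <= DEFAULT_METHYL_BORDER) and \
                (mean_m > DEFAULT_METHYL_BORDER)
        assert hits == 20

    def test_igs_sites_methylated_regardless_of_state(self, ref):
        spec = ArraySpec(copies=[CopySpec(3, 2, meth_state="U")] * 2)
        _, truth = simulate_array_read(ref, spec, errors=ERROR_FREE, seed=0)
        calls = simulate_methylation_calls(truth, seed=1)
        coding = truth.copies[0]["read_coding_interval"]
        igs = [c.posterior for c in calls
               if not any(a <= c.position < b for a, b in
                          (c2["read_coding_interval"] for c2 in truth.copies))]
        assert np.mean(igs) > 0.4

    def test_deterministic_under_seed(self, ref):
        spec = ArraySpec(copies=[CopySpec(3, 2)])
        _, truth = simulate_array_read(ref, spec, errors=ERROR_FREE, seed=0)
        a = simulate_methylation_calls(truth, seed=5)
        b = simulate_methylation_calls(truth, seed=5)
        assert [(c.position, c.posterior) for c in a] == \
            [(c.position, c.posterior) for c in b]

    def test_invalid_density_rejected(self, ref):
        spec = ArraySpec(copies=[CopySpec(3, 2)])
        _, truth = simulate_array_read(ref, spec, errors=ERROR_FREE, seed=0)
        with pytest.raises(ValueError):
            simulate_methylation_calls(truth, cpg_density=0)


class TestMarkovStates:
    def test_stationary_fraction_and_switch_rate(self):
        rng = np.random.default_rng(0)
        states = markov_methylation_states(50_000, 0.4, 0.05, rng)
        frac_u = states.count("U") / len(states)
        switches = sum(a != b for a, b in zip(states, states[1:]))
        assert frac_u == pytest.approx(0.4, abs=0.02)
        assert switches / (len(states) - 1) == pytest.approx(0.05, abs=0.005)


class TestSampleScenario:
    def test_fixed_seed_identical_sample(self, ref):
        sc = SampleScenario(n_rdna_reads=2, n_background=3)
        a = simulate_sample(ref, sc, seed=11)
        b = simulate_sample(ref, sc, seed=11)
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]
        assert a.truths.keys() == b.truths.keys()

    def test_truth_labels_cover_all_reads(self, ref):
        sc = SampleScenario(n_rdna_reads=2, n_background=2, n_decoys=1)
        sample = simulate_sample(ref, sc, seed=12)
        assert len(sample.reads) == 5
        assert {t.is_rdna for t in sample.truths.values()} == {True, False}
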