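import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdnarray.evaluation import bin_oracle
from rdnarray.methylation import (CopyMethylStatus, MethylCall,
                                  active_copy_analysis, bin_methylation,
                                  copy_methylation, correlate_45s_igs,
                                  correlate_r_repeat_methylation,
                                  estimate_copy_number, igs_methylation,
                                  methylation_adjacency,
                                  methylation_switch_rate,
                                  read_methylation_tsv, write_methylation_tsv)
from rdnarray.structure import CopySegment


def calls_at(pairs, read_id="r"):
    return [MethylCall(read_id, p, v) for p, v in pairs]


class TestBinning:
    def test_simple_bins(self):
        prof = bin_methylation(calls_at([(10, 1.0), (20, 1.0)]), 400)
        assert list(prof.bin_start) == [0]
        assert prof.avg_freq[0] == 1.0 and prof.thresh_freq[0] == 1.0

    def test_threshold_metric_counts_high_posteriors(self):
        prof = bin_methylation(calls_at([(10, 0.9), (20, 0.7)]), 400)
        assert prof.avg_freq[0] == pytest.approx(0.8)
        assert prof.thresh_freq[0] == pytest.approx(0.5)

    def test_empty_bins_excluded(self):
        prof = bin_methylation(calls_at([(450, 0.5)]), 1_000)
        assert list(prof.bin_start) == [400]

    def test_invalid_posterior_rejected(self):
        with pytest.raises(ValueError):
            bin_methylation(calls_at([(10, 1.5)]), 400)

    @given(st.data())
    @settings(derandomize=True, max_examples=50)
    def test_agrees_with_bruteforce_oracle(self, data):
        read_length = data.draw(st.integers(200, 3_000))
        n = data.draw(st.integers(1, 40))
        pos = data.draw(st.lists(st.integers(0, read_length - 1),
                                 min_size=n, max_size=n, unique=True))
        post = data.draw(st.lists(st.floats(0, 1), min_size=n, max_size=n))
        calls = sorted(calls_at(zip(pos, post)), key=lambda c: c.position)
        prof = bin_methylation(calls, read_length)
        oracle = bin_oracle(calls, read_length)
        got = {int(b): (int(k), float(a), float(t)) for b, k, a, t in
               zip(prof.bin_start, prof.n_cpg, prof.avg_freq, prof.thresh_freq)}
        assert set(got) == set(oracle)
        for b, (k, a, t) in oracle.items():
            assert got[b][0] == k
            assert got[b][1] == pytest.approx(a, abs=1e-12)
            assert got[b][2] == pytest.approx(t, abs=1e-12)


def segment(coding=(1_000, 2_000), igs=((2_000, 3_000),), complete=True):
    return CopySegment("r", 0, 0, 4_000, complete, "+",
                       coding_read_interval=coding, igs_read_intervals=igs)


class TestCopyMethylation:
    def test_unmethylated_copy(self):
        calls = calls_at([(p, 0.02) for p in range(1_000, 2_000, 20)])
        status = copy_methylation(segment(), calls)
        assert status.methyl_class == "unmethylated"
        assert status.mean_45s == pytest.approx(0.02)

    def test_methylated_copy(self):
        calls = calls_at([(p, 0.4) for p in range(1_000, 2_000, 20)])
        assert copy_methylation(segment(), calls).methyl_class == "methylated"

    def test_border_is_strict(self):
        calls = calls_at([(1_100, 0.1), (1_200, 0.1)])
        assert copy_methylation(segment(), calls).methyl_class == "unmethylated"

    def test_no_coding_calls_missing(self):
        assert copy_methylation(segment(), calls_at([(3_500, 0.5)])) is None


class TestIgsMethylation:
    def test_fully_methylated_igs(self):
        calls = calls_at([(p, 1.0) for p in range(2_000, 3_000, 50)])
        assert igs_methylation(segment(), calls) == 1.0

    def test_butterfly_only_cpgs_missing(self):
        # the eligible IGS intervals already exclude the Butterfly/Long span;
        # calls falling outside them yield no value
        calls = calls_at([(3_500, 1.0)])
        assert igs_methylation(segment(), calls) is None

    def test_mixed_posteriors_average(self):
        calls = calls_at([(2_100, 1.0), (2_200, 0.0)])
        assert igs_methylation(segment(), calls) == pytest.approx(0.5)


class TestStratifiedCorrelation:
    def test_noisy_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        statuses = []
        for i in range(100):
            m = float(rng.uniform(0.31, 0.95))
            statuses.append(CopyMethylStatus("r", i, m, 50, "methylated",
                                             igs_methylation=m + rng.normal(0, 0.01)))
        out = correlate_45s_igs(statuses)
        assert out["r"] > 0.9

    def test_constant_igs_undetermined(self):
        statuses = [CopyMethylStatus("r", i, 0.4 + 0.01 * i, 50, "methylated",
                                     igs_methylation=0.5) for i in range(20)]
        out = correlate_45s_igs(statuses)
        assert out["r"] is None and "variance" in out["note"]

    def test_small_stratum_undetermined(self):
        statuses = [CopyMethylStatus("r", i, 0.5, 50, "methylated", 0.5)
                    for i in range(5)]
        assert correlate_45s_igs(statuses)["r"] is None


def status_chain(classes, read_id="r", values=None):
    values = values or [0.02 if c == "U" else 0.5 for c in classes]
    return [CopyMethylStatus(read_id, i, v, 50,
                             "unmethylated" if c == "U" else "methylated")
            for i, (c, v) in enumerate(zip(classes, values))]


class TestSwitchRate:
    def test_single_switch(self):
        out = methylation_switch_rate(status_chain("UUMM"))
        assert out["rate"] == pytest.approx(1 / 3)
        assert out["mean_run_length"] == pytest.approx(3.0)

    def test_no_switches(self):
        assert methylation_switch_rate(status_chain("MMMM"))["rate"] == 0.0

    def test_alternating(self):
        assert methylation_switch_rate(status_chain("UMUM"))["rate"] == 1.0

    def test_no_pairs_undefined(self):
        assert methylation_switch_rate(status_chain("U"))["rate"] is None


class TestMethylationAdjacency:
    def test_adjacent_differences(self):
        statuses = status_chain("UUM", values=[0.0, 0.0, 0.9])
        out = methylation_adjacency(statuses, 50, seed=0)
        assert out["adjacent"] == [pytest.approx(0.0), pytest.approx(0.9)]

    def test_seeded_control_reproducible(self):
        statuses = status_chain("UMUM", values=[0.0, 0.9, 0.1, 0.8])
        a = methylation_adjacency(statuses, 100, seed=3)
        b = methylation_adjacency(statuses, 100, seed=3)
        assert a["control"] == b["control"]

    def test_no_multicopy_reads_empty(self):
        statuses = status_chain("U", read_id="a") + status_chain("M", read_id="b")
        out = methylation_adjacency(statuses, 10, seed=0)
        assert out["adjacent"] == [] and out["p"] is None


class TestCopyNumber:
    def test_zero_rdna(self):
        est = estimate_copy_number(0, 10**9, 44_800)
        assert est.copies_per_cell == 0

    def test_formula_example(self):
        est = estimate_copy_number(5, 1_000, 44_800, genome_size=6.2e9)
        # fraction 0.005 of a 6.2-Gb genome over a 44.8-kb unit
        assert round(est.copies_per_cell) == 692

    def test_linearity(self):
        a = estimate_copy_number(10, 1_000, 40_000).copies_per_cell
        b = estimate_copy_number(20, 1_000, 40_000).copies_per_cell
        assert b == pytest.approx(2 * a)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_copy_number(1, 10, 0)
        with pytest.raises(ValueError):
            estimate_copy_number(20, 10, 40_000)


class TestActiveCopyAnalysis:
    def test_constant_active_scenario(self):
        rng = np.random.default_rng(1)
        samples = [(float(n), 230.0 / n + rng.normal(0, 0.01))
                   for n in np.linspace(250, 700, 10)]
        out = active_copy_analysis(samples)
        assert out["A"] == pytest.approx(230, rel=0.1)
        assert out["r_proportion"] < -0.8

    def test_independent_proportion_weak_correlation(self):
        rng = np.random.default_rng(2)
        samples = [(float(n), 0.5 + rng.normal(0, 0.02))
                   for n in np.linspace(250, 700, 30)]
        out = active_copy_analysis(samples)
        assert abs(out["r_proportion"]) < 0.45

    def test_no_copy_number_variance_undetermined(self):
        out = active_copy_analysis([(400.0, 0.5)] * 6)
        assert out["A"] is None


class TestRRepeatCorrelation:
    def test_planted_monotone_dependence(self):
        rng = np.random.default_rng(3)
        r_vals = list(rng.integers(0, 5, 100))
        meth = [0.1 * r + rng.normal(0, 0.02) for r in r_vals]
        rows = correlate_r_repeat_methylation({"s1": (r_vals, meth)})
        assert rows[0]["rho"] > 0.8 and rows[0]["fdr_significant"]

    def test_constant_r_skipped(self):
        rows = correlate_r_repeat_methylation({"s1": ([2] * 20, [0.5] * 20)})
        assert rows[0]["skipped"]

    def test_too_few_copies_skipped(self):
        rows = correlate_r_repeat_methylation({"s1": ([1, 2, 3], [0.1, 0.2, 0.3])})
        assert rows[0]["skipped"]


def test_tsv_roundtrip(tmp_path):
    calls = calls_at([(10, 0.25), (300, 0.9)], read_id="a") + \
        calls_at([(5, 0.5)], read_id="b")
    p = tmp_path / "calls.tsv"
    write_methylation_tsv(calls, p)
    back = read_methylation_tsv(p)
    assert set(back) == {"a", "b"}
    assert [c.position for c in back["a"]] == [10, 300]
    assert back["a"][1].posterior == pytest.approx(0.9)
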