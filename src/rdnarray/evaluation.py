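"""Property-based evaluation scenarios over the synthetic generator.

Each function simulates a study condition with planted truth, runs the
relevant pipeline stages, and returns measured recovery/accuracy metrics.
They are shared by the test suite and by ``scripts/acceptance.py``; problem
sizes are chosen to finish on one CPU in a few minutes.
"""

from __future__ import annotations

import numpy as np

from . import methylation as meth
from . import repeats as rep
from . import structure as st
from .kmeralign import BuiltinAligner, revcomp
from .methylation import MethylCall
from .pipeline import run_sample
from .refmodel import circular_delta
from .seqio import Read
from .simdata import (ERROR_FREE, ArraySpec, CopySpec, ErrorModel,
                      SampleScenario, make_synthetic_reference,
                      markov_methylation_states, simulate_array_read,
                      simulate_methylation_calls, simulate_sample,
                      simulate_template_switch, simulate_true_palindrome)
from .splitmap import count_reference_gaps, map_splits, split_read


def _seeded(seed: int, salt: int) -> int:
    return int(np.random.default_rng((seed, salt)).integers(2**31))


def splitmap_roundtrip(seed: int, n_reads: int = 50) -> dict:
    """Error-free multi-unit reads must map every section at its planted spot.

    Half the reads are reverse-complemented.  Returns the mapped fraction,
    the fraction of sections at the exact planted position/strand, and the
    summed reference-gap count (all gaps spurious by construction).
    """
    ref = make_synthetic_reference(seed=_seeded(seed, 1))
    aligner = BuiltinAligner(ref)
    rng = np.random.default_rng(_seeded(seed, 2))
    L = ref.unit_length
    n_sections = n_mapped = n_exact = gaps = 0
    spec = ArraySpec(copies=[CopySpec(3, 2), CopySpec(3, 2)])
    for i in range(n_reads):
        phase = int(rng.integers(0, L))
        read, _ = simulate_array_read(ref, spec, start_phase=phase,
                                      errors=ERROR_FREE, seed=0,
                                      read_id=f"rt_{i}")
        flip = i % 2 == 1
        if flip:
            read = Read(read.read_id, revcomp(read.sequence), None)
        amap = map_splits(split_read(read), ref, aligner)
        total = len(read)
        for s in amap.splits:
            n_sections += 1
            if not s.mapped:
                continue
            n_mapped += 1
            if flip:
                expected = (phase + total - s.read_offset - s.length) % L
                ok = s.strand == "-"
            else:
                expected = (phase + s.read_offset) % L
                ok = s.strand == "+"
            if ok and circular_delta(expected, s.ref_pos, L) == 0:
                n_exact += 1
        gaps += count_reference_gaps(amap, ref)
    return {
        "n_sections": n_sections,
        "mapped_fraction": n_mapped / n_sections,
        "exact_fraction": n_exact / n_sections,
        "gap_count": gaps,
    }


def structural_detection(seed: int, n_mutated: int = 200, n_clean: int = 50,
                         n_satellite: int = 50,
                         errors: ErrorModel | None = None) -> dict:
    """Recovery of planted coding-region indels under sequencing noise.

    Mutated reads carry one 600-8000 nt deletion or duplication in the
    middle copy; detection requires an unsuppressed event whose magnitude is
    within 25% of the planted size.  Clean reads must yield no unsuppressed
    event, and reads whose only variation is satellite copy number must have
    every event suppressed.
    """
    if errors is None:
        errors = ErrorModel()
    ref = make_synthetic_reference(seed=_seeded(seed, 11))
    aligner = BuiltinAligner(ref)
    rng = np.random.default_rng(_seeded(seed, 12))

    detected = 0
    for i in range(n_mutated):
        size = int(rng.integers(600, 8001))
        etype = "deletion" if rng.random() < 0.5 else "duplication"
        pos = int(rng.integers(1000, max(1001, 9000 - size)))
        copies = [CopySpec(3, 2), CopySpec(3, 2, [(etype, pos, size)]),
                  CopySpec(3, 2)]
        read, _ = simulate_array_read(
            ref, ArraySpec(copies=copies), start_phase=int(rng.integers(15000, 35000)),
            errors=errors, seed=int(rng.integers(2**31)), read_id=f"mut_{i}")
        amap = map_splits(split_read(read), ref, aligner)
        unsup = [e for e in st.detect_structural_gaps(amap, ref)
                 if not e.suppressed]
        if any(abs(abs(e.deviation) - size) <= 0.25 * size for e in unsup):
            detected += 1

    false_events = 0
    for i in range(n_clean):
        read, _ = simulate_array_read(
            ref, ArraySpec(copies=[CopySpec(3, 2)] * 2),
            start_phase=int(rng.integers(0, ref.unit_length)),
            errors=errors, seed=int(rng.integers(2**31)), read_id=f"clean_{i}")
        amap = map_splits(split_read(read), ref, aligner)
        false_events += sum(1 for e in st.detect_structural_gaps(amap, ref)
                            if not e.suppressed)

    sat_events = sat_suppressed = 0
    for i in range(n_satellite):
        copies = [CopySpec(int(rng.integers(0, 5)), int(rng.integers(1, 3)))
                  for _ in range(3)]
        read, _ = simulate_array_read(
            ref, ArraySpec(copies=copies), start_phase=int(rng.integers(0, 10000)),
            errors=errors, seed=int(rng.integers(2**31)), read_id=f"sat_{i}")
        amap = map_splits(split_read(read), ref, aligner)
        for e in st.detect_structural_gaps(amap, ref):
            sat_events += 1
            sat_suppressed += e.suppressed
    return {
        "n_mutated": n_mutated,
        "sensitivity": detected / n_mutated,
        "false_unsuppressed_on_clean": false_events,
        "satellite_events": sat_events,
        "satellite_suppressed_fraction": (sat_suppressed / sat_events
                                          if sat_events else 1.0),
    }


def palindrome_triage(seed: int, n_artifacts: int = 200,
                      n_true: int = 50) -> dict:
    """Template-switch artifacts vs genuine palindromes.

    Every simulated artifact (complete first strand, uniformly terminated
    second strand) must land its inversion point at or after
    0.5 - split/read_length and be classed artifact-consistent.  Genuine
    palindromes with random framing must place a substantial share of
    inversion points in the former half and (without a planted quality
    drop) be classed candidate-real there.
    """
    ref = make_synthetic_reference(seed=_seeded(seed, 21))
    aligner = BuiltinAligner(ref)
    rng = np.random.default_rng(_seeded(seed, 22))
    errors = ErrorModel()
    spec = ArraySpec(copies=[CopySpec(3, 2)])

    n_called = n_latter = n_artifact_class = 0
    for i in range(n_artifacts):
        base, _ = simulate_array_read(
            ref, spec, start_phase=int(rng.integers(0, ref.unit_length)),
            errors=errors, seed=int(rng.integers(2**31)), read_id=f"art_{i}")
        read, _ = simulate_template_switch(base, "uniform",
                                           seed=int(rng.integers(2**31)))
        amap = map_splits(split_read(read), ref, aligner)
        call = st.detect_inversion(amap)
        if call is None or call.complex:
            continue
        n_called += 1
        bound = 0.5 - amap.split_length / amap.read_length
        if call.relative_position >= bound:
            n_latter += 1
        call.quality_drop = st.detect_quality_drop(read.qualities,
                                                   call.read_offset)
        if st.classify_palindrome(call) == "artifact_consistent":
            n_artifact_class += 1

    n_true_called = n_former = n_candidate = 0
    for i in range(n_true):
        # stratified framing: fold points evenly span the admissible window
        read, _ = simulate_true_palindrome(ref, n_units=1,
                                           seed=int(rng.integers(2**31)),
                                           errors=errors,
                                           frame=1.0 - (i + 0.5) / n_true,
                                           read_id=f"pal_{i}")
        amap = map_splits(split_read(read), ref, aligner)
        call = st.detect_inversion(amap)
        if call is None or call.complex:
            continue
        n_true_called += 1
        if call.relative_position < 0.5:
            n_former += 1
            call.quality_drop = st.detect_quality_drop(read.qualities,
                                                       call.read_offset)
            if st.classify_palindrome(call) == "candidate_real":
                n_candidate += 1
    return {
        "n_artifacts_called": n_called,
        "artifact_latter_half_fraction": n_latter / n_called if n_called else 0.0,
        "artifact_classified_fraction": (n_artifact_class / n_called
                                         if n_called else 0.0),
        "n_true_called": n_true_called,
        "true_former_half_fraction": (n_former / n_true_called
                                      if n_true_called else 0.0),
        "true_candidate_fraction": (n_candidate / n_former
                                    if n_former else 1.0),
    }


def repeat_recovery(seed: int, n_copies_noisy: int = 300,
                    n_copies_clean: int = 50) -> dict:
    """Planted per-copy (delta R, delta Butterfly/Long) recovery."""
    ref = make_synthetic_reference(seed=_seeded(seed, 31))
    aligner = BuiltinAligner(ref)

    def run(total_copies: int, errors: ErrorModel, salt: int,
            copies_per_read: int = 3) -> list[tuple[int, int]]:
        rng = np.random.default_rng(_seeded(seed, salt))
        diffs: list[tuple[int, int]] = []
        while len(diffs) < total_copies:
            copies = [CopySpec(int(rng.integers(0, 5)), int(rng.integers(1, 3)))
                      for _ in range(copies_per_read)]
            read, truth = simulate_array_read(
                ref, ArraySpec(copies=copies),
                start_phase=int(rng.integers(2000, 10000)), errors=errors,
                seed=int(rng.integers(2**31)))
            amap = map_splits(split_read(read), ref, aligner)
            segs = st.segment_copies(amap, ref)
            est = {e.copy_index: e for e in
                   rep.estimate_repeat_lengths(read, segs, ref) if e.complete}
            truth_complete = [c for c in truth.copies if c["complete"]]
            for e, c in zip(sorted(est.values(), key=lambda e: e.copy_index),
                            truth_complete):
                if e.delta_r is None or e.delta_bl is None:
                    diffs.append((10**6, 10**6))  # missing counts as a miss
                else:
                    diffs.append((e.delta_r - c["delta_r"],
                                  e.delta_bl - c["delta_bl"]))
        return diffs[:total_copies]

    noisy = run(n_copies_noisy, ErrorModel(), 32)
    clean = run(n_copies_clean, ERROR_FREE, 33, copies_per_read=2)
    within_150 = np.mean([max(abs(a), abs(b)) <= 150 for a, b in noisy])
    max_clean = max(max(abs(a), abs(b)) for a, b in clean)
    return {
        "n_noisy": len(noisy),
        "recovered_within_150_fraction": float(within_150),
        "n_clean": len(clean),
        "max_error_clean": int(max_clean),
    }


def homogenization_statistic(seed: int, n_pairs: int = 200,
                             n_null_replicates: int = 100) -> dict:
    """Adjacent-copy similarity test: power under correlation, size under iid.

    Per-copy repeat deltas are drawn from the satellite copy-number
    distribution; under homogenization an adjacent copy clones its
    neighbour with probability q = 0.8.  The one-sided rank test must
    reject at p < 0.01 with 200 adjacent pairs, and reject in only ~1% of
    seeded iid replicates.
    """
    value_pool = np.array([-4500, 0, 0, 0, 680, 1360])

    def sample_estimates(rng, q: float, n_reads: int,
                         copies_per_read: int = 2) -> list[rep.RepeatLengthEstimate]:
        out = []
        for r in range(n_reads):
            vals = []
            for i in range(copies_per_read):
                if i > 0 and rng.random() < q:
                    vals.append(vals[-1])
                else:
                    vals.append(int(rng.choice(value_pool)))
            for i, v in enumerate(vals):
                out.append(rep.RepeatLengthEstimate(f"r{r}", i, v, v))
        return out

    rng = np.random.default_rng(_seeded(seed, 41))
    est = sample_estimates(rng, q=0.8, n_reads=n_pairs)
    adj, _ = rep.adjacent_pair_differences(est)
    pool = [e.delta_r for e in est]
    control = rep.randomized_pair_differences(pool, 500,
                                              seed=_seeded(seed, 42))
    _, p_corr = rep.compare_adjacent_vs_random(adj, control)

    rejections = 0
    for i in range(n_null_replicates):
        rng_i = np.random.default_rng(_seeded(seed, 1000 + i))
        est = sample_estimates(rng_i, q=0.0, n_reads=n_pairs)
        adj, _ = rep.adjacent_pair_differences(est)
        pool = [e.delta_r for e in est]
        control = rep.randomized_pair_differences(pool, 500,
                                                  seed=_seeded(seed, 2000 + i))
        _, p = rep.compare_adjacent_vs_random(adj, control)
        rejections += p < 0.01
    return {
        "n_pairs": n_pairs,
        "correlated_p": float(p_corr),
        "null_rejections": rejections,
        "null_replicates": n_null_replicates,
    }


def bin_oracle(calls: list[MethylCall], read_length: int, bin_size: int = 200,
               threshold: float = 0.8) -> dict[int, tuple[int, float, float]]:
    """Independent per-bin re-computation: {bin start: (n, avg, thresh)}."""
    bins: dict[int, list[float]] = {}
    for c in calls:
        bins.setdefault((c.position // bin_size) * bin_size, []).append(c.posterior)
    return {b: (len(v), sum(v) / len(v),
                sum(1 for x in v if x >= threshold) / len(v))
            for b, v in bins.items()}


def methylation_metrics(seed: int, n_binsets: int = 1000,
                        n_class_copies: int = 2000, cpg_per_copy: int = 50,
                        n_switch_pairs: int = 2000) -> dict:
    """Binning oracle agreement, class recovery, and switch-rate calibration."""
    rng = np.random.default_rng(_seeded(seed, 51))

    agree = 0
    for _ in range(n_binsets):
        read_length = int(rng.integers(600, 4000))
        n = int(rng.integers(1, 60))
        pos = np.sort(rng.choice(read_length, size=min(n, read_length),
                                 replace=False))
        calls = [MethylCall("x", int(p), float(rng.random())) for p in pos]
        prof = meth.bin_methylation(calls, read_length)
        oracle = bin_oracle(calls, read_length)
        got = {int(b): (int(n_), float(a), float(t)) for b, n_, a, t in
               zip(prof.bin_start, prof.n_cpg, prof.avg_freq, prof.thresh_freq)}
        ok = set(got) == set(oracle) and all(
            got[b][0] == oracle[b][0]
            and abs(got[b][1] - oracle[b][1]) < 1e-12
            and abs(got[b][2] - oracle[b][2]) < 1e-12 for b in oracle)
        agree += ok

    correct = 0
    for _ in range(n_class_copies):
        state = "U" if rng.random() < 0.5 else "M"
        a, b = (1, 20) if state == "U" else (8, 8)
        mean = float(np.mean(rng.beta(a, b, size=cpg_per_copy)))
        cls = "methylated" if mean > meth.DEFAULT_METHYL_BORDER else "unmethylated"
        correct += (cls == "methylated") == (state == "M")

    true_rate = 0.05
    statuses = []
    n_chains = n_switch_pairs // 2
    for r in range(n_chains):
        states = markov_methylation_states(3, 0.5, true_rate, rng)
        for i, s in enumerate(states):
            statuses.append(meth.CopyMethylStatus(
                f"c{r}", i, 0.02 if s == "U" else 0.5, cpg_per_copy,
                "unmethylated" if s == "U" else "methylated"))
    switch = meth.methylation_switch_rate(statuses)
    n_pairs = switch["n_pairs"]
    se = float(np.sqrt(true_rate * (1 - true_rate) / n_pairs))
    return {
        "oracle_agreement_fraction": agree / n_binsets,
        "class_accuracy": correct / n_class_copies,
        "switch_rate": switch["rate"],
        "switch_true_rate": true_rate,
        "switch_pairs": n_pairs,
        "switch_z": abs(switch["rate"] - true_rate) / se,
    }


def copy_number_recovery(seed: int, n_rdna: int = 8, n_background: int = 120
                         ) -> dict:
    """Depth-ratio rDNA fraction recovery through WGS screening."""
    ref = make_synthetic_reference(seed=_seeded(seed, 61))
    sc = SampleScenario(mode="wgs", n_rdna_reads=n_rdna,
                        n_background=n_background, units_per_read=(2, 2))
    sample = simulate_sample(ref, sc, seed=_seeded(seed, 62))
    planted_rdna = sum(len(r) for r in sample.reads
                       if sample.truths[r.read_id].is_rdna)
    total = sum(len(r) for r in sample.reads)
    summary, _ = run_sample(sample.reads, ref, seed=_seeded(seed, 63))
    measured = summary.copy_number["rdna_fraction"]
    planted = planted_rdna / total
    return {
        "planted_fraction": planted,
        "measured_fraction": measured,
        "relative_error": abs(measured - planted) / planted,
        "n_reads": len(sample.reads),
    }


def active_copy_recovery(seed: int, active: float = 230.0,
                         n_samples: int = 12, copies_per_sample: int = 400,
                         cpg_per_copy: int = 50) -> dict:
    """Constant-active-copy scenario: fit A and the copy-number correlation.

    Sample totals span 250-700 copies per cell; each sample's unmethylated
    proportion is measured by classifying simulated bimodal posteriors, so
    the fit sees realistic classification noise.
    """
    rng = np.random.default_rng(_seeded(seed, 71))
    totals = np.linspace(250, 700, n_samples)
    points = []
    for N in totals:
        p_u = active / N
        n_unmeth = 0
        for _ in range(copies_per_sample):
            state_u = rng.random() < p_u
            a, b = (1, 20) if state_u else (8, 8)
            mean = float(np.mean(rng.beta(a, b, size=cpg_per_copy)))
            n_unmeth += mean <= meth.DEFAULT_METHYL_BORDER
        points.append((float(N), n_unmeth / copies_per_sample))
    result = meth.active_copy_analysis(points)
    return {
        "fitted_active_copies": result["A"],
        "true_active_copies": active,
        "relative_error": abs(result["A"] - active) / active,
        "r_copies_vs_proportion": result["r_proportion"],
        "n_samples": n_samples,
    }


def determinism_check(seed: int) -> dict:
    """The pipeline summary must be bit-identical across repeat runs."""
    import json

    ref = make_synthetic_reference(seed=_seeded(seed, 81))
    sc = SampleScenario(mode="wgs", n_rdna_reads=4, n_background=10)

    def one() -> str:
        sample = simulate_sample(ref, sc, seed=_seeded(seed, 82))
        summary, _ = run_sample(sample.reads, ref,
                                methyl_calls=sample.methyl_calls,
                                seed=_seeded(seed, 83))
        return json.dumps(summary.to_json(), sort_keys=True)

    return {"identical": float(one() == one())}
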