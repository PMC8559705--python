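"""End-to-end orchestration: screen -> map -> structure -> repeats -> methylation.

One :func:`process_read` call runs all per-read stages; :func:`run_sample`
aggregates a collection of reads into a :class:`SampleSummary` with the
sample-level statistics (noncanonical and palindrome rates, IGS type,
copy-number estimate, methylation summaries).  :func:`run_pipeline` is the
config-driven entry point used by the command line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import methylation as meth
from . import repeats as rep
from . import screen as scr
from . import structure as st
from .kmeralign import make_aligner
from .refmodel import ReferenceModel, load_reference
from .seqio import Read, read_fastq
from .splitmap import (DEFAULT_SPLIT_LENGTH, ReadAlignmentMap, map_splits,
                       split_read)


@dataclass
class ReadResult:
    read_id: str
    screen: scr.ScreenResult
    amap: ReadAlignmentMap
    gap_events: list[st.GapEvent] = field(default_factory=list)
    inversion: st.InversionCall | None = None
    segments: list[st.CopySegment] = field(default_factory=list)
    estimates: list[rep.RepeatLengthEstimate] = field(default_factory=list)
    statuses: list[meth.CopyMethylStatus] = field(default_factory=list)

    @property
    def n_complete_copies(self) -> int:
        return sum(1 for s in self.segments if s.complete)


@dataclass
class SampleSummary:
    sample_id: str
    n_reads: int = 0
    n_pass: int = 0
    total_bases: int = 0
    rdna_bases: int = 0
    copies_counted: int = 0
    noncanonical: dict = field(default_factory=dict)
    igs_type: dict = field(default_factory=dict)
    copy_number: dict = field(default_factory=dict)
    methylation: dict = field(default_factory=dict)
    adjacency: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return asdict(self)


def process_read(read: Read, ref: ReferenceModel, aligner, *,
                 mode: str = "wgs", qc: dict[str, bool] | None = None,
                 cut_sites: list[int] | None = None,
                 calls: list[meth.MethylCall] | None = None,
                 split_length: int = DEFAULT_SPLIT_LENGTH,
                 structural_threshold: int = st.DEFAULT_STRUCTURAL_THRESHOLD,
                 inversion_fraction: float = st.DEFAULT_MIN_OPPOSITE_FRACTION,
                 methyl_border: float = meth.DEFAULT_METHYL_BORDER,
                 ) -> ReadResult:
    """Run every per-read stage; failed screening short-circuits the rest."""
    splits = split_read(read, split_length)
    amap = map_splits(splits, ref, aligner)
    if mode == "cas9":
        screen_result = scr.screen_cas9_read(read, amap, cut_sites or [], ref)
    else:
        screen_result = scr.screen_wgs_read(read, amap, qc, ref=ref)
    result = ReadResult(read.read_id, screen_result, amap)
    if screen_result.verdict != "pass":
        return result

    result.gap_events = st.detect_structural_gaps(amap, ref, structural_threshold)
    result.inversion = st.detect_inversion(amap, inversion_fraction)
    if result.inversion is not None:
        if not result.inversion.complex and read.qualities is not None:
            result.inversion.quality_drop = st.detect_quality_drop(
                read.qualities, result.inversion.read_offset)
        if not result.inversion.complex:
            st.classify_palindrome(result.inversion)
        return result  # inverted reads are not segmented into copies

    result.segments = st.segment_copies(amap, ref)
    result.estimates = rep.estimate_repeat_lengths(read, result.segments, ref)
    if calls:
        for seg in result.segments:
            if not seg.complete:
                continue
            status = meth.copy_methylation(seg, calls, methyl_border)
            if status is None:
                continue
            status.igs_methylation = meth.igs_methylation(seg, calls)
            result.statuses.append(status)
    return result


def run_sample(reads: list[Read], ref: ReferenceModel, *,
               sample_id: str = "sample", mode: str = "wgs",
               aligner=None, qc: dict[str, bool] | None = None,
               methyl_calls: dict[str, list[meth.MethylCall]] | None = None,
               genome_size: float = meth.DEFAULT_GENOME_SIZE,
               seed: int = 0, n_random_pairs: int = 500,
               **kwargs) -> tuple[SampleSummary, list[ReadResult]]:
    """Process all reads of one sample and aggregate the summary statistics."""
    if aligner is None:
        aligner = make_aligner(ref)
    cut_sites = scr.locate_cut_sites(ref) if mode == "cas9" else None
    results: list[ReadResult] = []
    for read in reads:
        calls = (methyl_calls or {}).get(read.read_id)
        results.append(process_read(read, ref, aligner, mode=mode, qc=qc,
                                    cut_sites=cut_sites, calls=calls, **kwargs))

    summary = SampleSummary(sample_id=sample_id, n_reads=len(reads))
    summary.total_bases = sum(len(r) for r in reads)
    passing = [r for r in results if r.screen.verdict == "pass"]
    summary.n_pass = len(passing)
    by_id = {r.read_id: r for r in results}
    summary.rdna_bases = sum(len(read) for read in reads
                             if by_id[read.read_id].screen.verdict == "pass")
    summary.copies_counted = sum(r.n_complete_copies for r in passing)

    read_records = []
    for r in passing:
        read_records.append({
            "n_complete_copies": r.n_complete_copies,
            "n_unsuppressed_events": sum(1 for g in r.gap_events
                                         if not g.suppressed),
            "palindrome_class": (r.inversion.classification
                                 if r.inversion else None),
        })
    summary.noncanonical = st.summarize_noncanonical(read_records)

    estimates = [e for r in passing for e in r.estimates if e.complete]
    igs = rep.classify_igs_type([e.delta_bl for e in estimates],
                                sample_id=sample_id)
    summary.igs_type = {"type": igs.igs_type,
                        "short_proportion": igs.short_proportion,
                        "n_copies": igs.n_copies}

    adjacency: dict = {}
    r_adj, bl_adj = rep.adjacent_pair_differences(estimates)
    for label, adj, values in (
            ("r", r_adj, [e.delta_r for e in estimates]),
            ("bl", bl_adj, [e.delta_bl for e in estimates])):
        informative = [v for v in values if v is not None]
        if adj and len(informative) >= 2:
            control = rep.randomized_pair_differences(
                informative, n_random_pairs, seed)
            stat, p = rep.compare_adjacent_vs_random(adj, control)
            adjacency[label] = {"n_adjacent": len(adj), "statistic": stat, "p": p}
        else:
            adjacency[label] = {"n_adjacent": len(adj), "statistic": None, "p": None}

    statuses = [s for r in passing for s in r.statuses]
    if statuses:
        n_unmeth = sum(1 for s in statuses if s.methyl_class == "unmethylated")
        switch = meth.methylation_switch_rate(statuses)
        madj = meth.methylation_adjacency(statuses, n_random_pairs, seed + 1)
        corr = meth.correlate_45s_igs(statuses)
        summary.methylation = {
            "n_classified_copies": len(statuses),
            "unmethylated_proportion": n_unmeth / len(statuses),
            "switch_rate": switch["rate"],
            "switch_pairs": switch["n_pairs"],
            "igs_45s_correlation": corr,
        }
        adjacency["methylation"] = {"n_adjacent": len(madj["adjacent"]),
                                    "statistic": madj["statistic"],
                                    "p": madj["p"]}
    summary.adjacency = adjacency

    cn = meth.estimate_copy_number(summary.rdna_bases, summary.total_bases,
                                   ref.unit_length, genome_size, sample_id) \
        if summary.total_bases else None
    if cn is not None:
        summary.copy_number = {
            "rdna_fraction": cn.rdna_fraction,
            "copies_per_cell": round(cn.copies_per_cell),
            "genome_size": genome_size,
        }
    return summary, results


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None
                 ) -> SampleSummary:
    """Config-driven run: load inputs, process the sample, write artifacts.

    The config (dict, or path to a YAML file) names the reference FASTA/BED,
    the reads FASTQ, optional methylation TSV and sequencing summary, the
    mode, and any threshold overrides.  Outputs (summary JSON, per-section
    alignment table, per-copy tables) go to ``out_dir``.
    """
    import yaml

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    ref = load_reference(
        config["reference"], config["annotation"],
        anchor_positions=config.get("anchor_positions",
                                    list(ReferenceModel.__dataclass_fields__
                                         ["anchor_positions"].default)),
        anchor_length=config.get("anchor_length", 500),
    )
    reads = list(read_fastq(config["reads"]))
    methyl_calls = None
    if config.get("methylation_calls"):
        methyl_calls = meth.read_methylation_tsv(config["methylation_calls"])
    qc = None
    if config.get("sequencing_summary"):
        qc = scr.read_sequencing_summary(config["sequencing_summary"])

    kwargs = {k: config[k] for k in
              ("split_length", "structural_threshold", "inversion_fraction",
               "methyl_border") if k in config}
    summary, results = run_sample(
        reads, ref,
        sample_id=config.get("sample_id", "sample"),
        mode=config.get("mode", "wgs"),
        aligner=make_aligner(ref, config.get("aligner", "builtin")),
        qc=qc, methyl_calls=methyl_calls,
        genome_size=config.get("genome_size", meth.DEFAULT_GENOME_SIZE),
        seed=int(config.get("seed", 0)), **kwargs)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .splitmap import write_alignment_table
        write_alignment_table([r.amap for r in results], out / "alignments.tsv")
        scr.write_screen_report([r.screen for r in results], out / "screen.tsv")
        rep.write_estimates_table(
            [e for r in results for e in r.estimates], out / "repeat_lengths.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary.to_json(), fh, indent=2, sort_keys=True)
    return summary
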