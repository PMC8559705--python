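"""Per-copy segmentation and noncanonical-structure detection.

A canonical tandem array maps as a staircase of diagonals wrapping at the
unit boundary.  Three analyses read deviations off the split map:

* :func:`segment_copies` places copy boundaries where the mapped sections
  cross the reference origin, yielding one :class:`CopySegment` per unit.
* :func:`detect_structural_gaps` flags section pairs whose spacing deviates
  by more than 500 nt from expectation — large duplications/deletions —
  while suppressing events confined to the naturally length-variable R and
  Butterfly/Long satellite regions.
* Inversion triage: reads with a substantial opposite-strand fraction are
  palindromic.  Nanopore template switching (the sequencer continuing onto
  the complementary strand) creates *fake* palindromes whose inversion point
  sits at or after the read centre and is typically followed by a quality
  drop; a genuine genomic palindrome can place the inversion point anywhere
  and should recur across reads at the same unit coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .refmodel import ReferenceModel, circular_delta
from .splitmap import ReadAlignmentMap, SplitAlignment, consecutive_mapped_pairs, pair_deviation

DEFAULT_STRUCTURAL_THRESHOLD = 500
DEFAULT_MIN_OPPOSITE_FRACTION = 0.10
DEFAULT_BREAKPOINT_TOLERANCE = 500
MIN_DOMINANT_FRACTION = 0.9


class InvertedReadError(ValueError):
    """Raised when copy segmentation is attempted on an inverted read."""


@dataclass
class CopySegment:
    """One rDNA unit's span within a read (read-space, 0-based half-open)."""

    read_id: str
    index: int
    read_start: int
    read_end: int
    complete: bool
    strand: str
    coding_read_interval: tuple[int, int] | None = None
    igs_read_intervals: tuple[tuple[int, int], ...] = ()

    @property
    def span(self) -> int:
        return self.read_end - self.read_start


@dataclass(frozen=True)
class GapEvent:
    read_id: str
    read_offset: int           # offset of the first flanking section
    expected: int              # expected unit-space displacement (bases)
    observed: int              # observed circular displacement (bases)
    deviation: int             # observed - expected, read-direction sign
    suppressed: bool           # both flanks inside a variable satellite region
    event_class: str           # "deletion" (positive) / "duplication" (negative)
    flank_regions: tuple[str, str] = ("", "")


@dataclass
class InversionCall:
    read_id: str
    read_offset: int           # inversion point, read space
    relative_position: float   # offset / read length
    opposite_fraction: float
    breakpoint_ref: int        # unit-space coordinate of the breakpoint
    orientation: tuple[str, str]
    complex: bool = False      # more than one strand transition
    resolution: float = 0.0    # localization resolution, split/read_length
    quality_drop: bool | None = None
    classification: str | None = None


def _dominant_mapped(amap: ReadAlignmentMap) -> list[SplitAlignment]:
    return [s for s in amap.mapped_splits if s.strand == amap.dominant_strand]


def segment_copies(amap: ReadAlignmentMap, ref: ReferenceModel) -> list[CopySegment]:
    """Segment a non-inverted read into per-unit copy segments.

    A copy boundary is placed wherever consecutive mapped sections straddle
    the reference origin in the dominant direction; complete segments lie
    between two successive crossings, partial leading/trailing segments are
    flagged incomplete.  The coding and (Butterfly/Long-excluded) IGS
    sub-intervals of each segment are taken from its member sections'
    reference regions.
    """
    if amap.dominant_fraction < MIN_DOMINANT_FRACTION:
        raise InvertedReadError(
            f"read {amap.read_id}: dominant strand fraction "
            f"{amap.dominant_fraction:.2f} < {MIN_DOMINANT_FRACTION}; run "
            "inversion analysis first")
    L = ref.unit_length
    strand = amap.dominant_strand
    sections = _dominant_mapped(amap)
    if not sections:
        return []

    boundaries: list[int] = []
    for a, b in zip(sections, sections[1:]):
        delta = circular_delta(a.ref_pos, b.ref_pos, L)
        if strand == "+" and delta > 0 and b.ref_pos < a.ref_pos:
            boundaries.append(a.read_offset + (L - a.ref_pos))
        elif strand == "-" and delta < 0 and b.ref_pos > a.ref_pos:
            boundaries.append(a.read_offset + a.ref_pos + a.length)

    edges = [0] + boundaries + [amap.read_length]
    # a leading/trailing segment is still a complete copy when the read
    # itself starts or ends at the unit origin (within a small tolerance)
    tol = 150
    first, last = sections[0], sections[-1]
    if strand == "+":
        origin_at_start = first.read_offset - first.ref_pos >= -tol
        end_origin = last.read_offset + (L - last.ref_pos)
    else:
        origin_at_start = first.read_offset + first.ref_pos + first.length >= L - tol
        end_origin = last.read_offset + last.length + last.ref_pos
    origin_at_end = end_origin <= amap.read_length + tol

    segments: list[CopySegment] = []
    for start, end in zip(edges, edges[1:]):
        if end - start <= 0:
            continue
        start_ok = start in boundaries or (start == 0 and origin_at_start)
        end_ok = end in boundaries or (end == amap.read_length and origin_at_end)
        seg = CopySegment(amap.read_id, len(segments), start, end,
                          start_ok and end_ok, strand)
        _annotate_segment(seg, amap, ref)
        segments.append(seg)
    return segments


def _annotate_segment(seg: CopySegment, amap: ReadAlignmentMap,
                      ref: ReferenceModel) -> None:
    """Fill coding/IGS read-space sub-intervals from member sections."""
    coding: list[tuple[int, int]] = []
    igs: list[tuple[int, int]] = []
    for s in amap.mapped_splits:
        if s.strand != seg.strand:
            continue
        if not (seg.read_start <= s.read_offset < seg.read_end):
            continue
        region = ref.region_of(s.ref_pos)
        iv = (s.read_offset, s.read_offset + s.length)
        if region == "coding":
            coding.append(iv)
        elif region in ("r_repeat", "igs_other"):
            igs.append(iv)  # butterfly_long excluded: few CpGs, variable length
    if coding:
        seg.coding_read_interval = (min(a for a, _ in coding),
                                    max(b for _, b in coding))
    seg.igs_read_intervals = tuple(_merge_intervals(igs))


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for a, b in sorted(ivs):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _flank_region(ref: ReferenceModel, s: SplitAlignment, dilation: int) -> str:
    """Region of a flanking section for the suppression rule.

    The section's reference midpoint is tested against the satellite
    intervals dilated by the junction's read-space span, so that variation
    junctions at a satellite block's edge (e.g. loss of the outermost or of
    every repeat unit) still count as inside the naturally variable region.
    """
    mid = (s.ref_pos + s.length // 2) % ref.unit_length
    for label, (lo, hi) in (("r_repeat", ref.r_repeat_interval),
                            ("butterfly_long", ref.butterfly_long_interval)):
        if lo - dilation <= mid < hi + dilation:
            return label
    return ref.region_of(mid)


def detect_structural_gaps(amap: ReadAlignmentMap, ref: ReferenceModel,
                           threshold: int = DEFAULT_STRUCTURAL_THRESHOLD
                           ) -> list[GapEvent]:
    """Large spacing deviations between consecutive mapped same-strand sections.

    Deviations strictly above ``threshold`` in absolute value are emitted.
    Positive deviation = reference sequence skipped between the flanks
    (deletion in the read); negative = extra read sequence (duplication).
    Events whose flanking sections both start inside the R repeat, or both
    inside the Butterfly/Long repeat, are marked suppressed: length variation
    there is natural and not counted as noncanonical.
    """
    events: list[GapEvent] = []
    for a, b in consecutive_mapped_pairs(amap):
        if a.strand != b.strand:
            continue
        dev = pair_deviation(a, b, ref.unit_length)
        if abs(dev) <= threshold:
            continue
        # flank sections sit up to one junction span outside the satellite
        # block when the breakpoint section itself maps to the other side
        dilation = b.read_offset - a.read_offset + a.length
        ra = _flank_region(ref, a, dilation)
        rb = _flank_region(ref, b, dilation)
        suppressed = (ra == rb == "r_repeat") or (ra == rb == "butterfly_long")
        expected = b.read_offset - a.read_offset
        events.append(GapEvent(
            read_id=amap.read_id,
            read_offset=a.read_offset,
            expected=expected,
            observed=expected + dev,
            deviation=dev,
            suppressed=suppressed,
            event_class="deletion" if dev > 0 else "duplication",
            flank_regions=(ra, rb),
        ))
    return events


def detect_inversion(amap: ReadAlignmentMap,
                     min_opposite_fraction: float = DEFAULT_MIN_OPPOSITE_FRACTION
                     ) -> InversionCall | None:
    """Label a read inverted when its opposite-strand share exceeds the cutoff.

    The cutoff is strict: exactly ``min_opposite_fraction`` is not inverted.
    Returns an :class:`InversionCall` locating the inversion point, or None.
    """
    mapped = amap.mapped_splits
    if not mapped:
        return None
    n_opposite = sum(1 for s in mapped if s.strand != amap.dominant_strand)
    if n_opposite <= min_opposite_fraction * len(mapped):
        return None
    return locate_inversion_point(amap, opposite_fraction=n_opposite / len(mapped))


def locate_inversion_point(amap: ReadAlignmentMap,
                           opposite_fraction: float | None = None
                           ) -> InversionCall:
    """Place the inversion point between the two strand runs of the read.

    The offset is the midpoint between the last section of the first strand
    run and the first section of the second run.  Reads with more than one
    strand transition carry ``complex=True`` and no single point is claimed
    (the first transition is reported for reference).
    """
    mapped = amap.mapped_splits
    runs: list[list[SplitAlignment]] = []
    for s in mapped:
        if runs and runs[-1][0].strand == s.strand:
            runs[-1].append(s)
        else:
            runs.append([s])
    if len(runs) < 2:
        raise ValueError(f"read {amap.read_id}: no strand transition")
    if opposite_fraction is None:
        n_opp = sum(1 for s in mapped if s.strand != amap.dominant_strand)
        opposite_fraction = n_opp / len(mapped)

    first, second = runs[0], runs[1]
    last_a = first[-1]
    first_b = second[0]
    offset = ((last_a.read_offset + last_a.length) + first_b.read_offset) // 2
    return InversionCall(
        read_id=amap.read_id,
        read_offset=offset,
        relative_position=offset / amap.read_length,
        opposite_fraction=opposite_fraction,
        breakpoint_ref=last_a.ref_pos,
        orientation=(last_a.strand, first_b.strand),
        complex=len(runs) > 2,
        resolution=amap.split_length / amap.read_length if amap.read_length else 0.0,
    )


def detect_quality_drop(qualities, inversion_offset: int, bin_size: int = 200,
                        drop: float = 5.0, span: int = 3,
                        window: int = 2000) -> bool | None:
    """Test for a sustained Phred-quality drop just after the inversion point.

    Qualities are binned from the read start; the mean of the ``span`` bins
    preceding the inversion is compared with the bins inside ``window`` after
    it.  True when at least ``span`` consecutive post-inversion bins each sit
    ``drop`` or more below the pre-inversion mean.  Returns None
    (undetermined) when the inversion lies within ``window`` of the read end.
    """
    q = np.asarray(qualities, dtype=float)
    n = len(q)
    if n - inversion_offset < window:
        return None
    n_bins = n // bin_size
    if n_bins == 0:
        return None
    means = q[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    inv_bin = inversion_offset // bin_size
    pre = means[max(0, inv_bin - span): inv_bin]
    if len(pre) == 0:
        return None
    pre_mean = pre.mean()
    post = means[inv_bin + 1: min(n_bins, inv_bin + 1 + window // bin_size)]
    below = post <= pre_mean - drop
    run = 0
    for flag in below:
        run = run + 1 if flag else 0
        if run >= span:
            return True
    return False


def classify_palindrome(call: InversionCall) -> str:
    """Artifact triage of a palindromic read from its inversion geometry.

    Template-switch artifacts place the inversion at or after the read
    centre: ``relative_position >= 0.5`` is artifact-consistent, judged at
    the inversion point's localization resolution (one section length).  A
    former-half inversion with a quality drop is dubious (it shares the
    artifact's signature); without a drop it is a candidate real palindrome.
    """
    if call.relative_position >= 0.5 - call.resolution:
        cls = "artifact_consistent"
    elif call.quality_drop:
        cls = "dubious"
    else:
        cls = "candidate_real"
    call.classification = cls
    return cls


def cluster_inversion_breakpoints(calls: list[InversionCall], ref: ReferenceModel,
                                  breakpoint_tolerance: int = DEFAULT_BREAKPOINT_TOLERANCE
                                  ) -> list[dict]:
    """Single-linkage clusters of inversion breakpoints in unit space.

    Calls with the same flank orientation whose breakpoints lie within the
    tolerance are linked; groups of two or more are recurrent (a recurring
    breakpoint supports a genuine genomic palindrome rather than independent
    sequencing artifacts).
    """
    L = ref.unit_length
    groups: list[dict] = []
    by_orient: dict[tuple[str, str], list[InversionCall]] = {}
    for c in calls:
        by_orient.setdefault(c.orientation, []).append(c)
    for orientation, members in by_orient.items():
        members = sorted(members, key=lambda c: c.breakpoint_ref)
        clusters: list[list[InversionCall]] = [[members[0]]]
        for c in members[1:]:
            if c.breakpoint_ref - clusters[-1][-1].breakpoint_ref <= breakpoint_tolerance:
                clusters[-1].append(c)
            else:
                clusters.append([c])
        # circular wrap: first and last clusters may join across the origin
        if len(clusters) > 1:
            gap = (clusters[0][0].breakpoint_ref + L) - clusters[-1][-1].breakpoint_ref
            if gap <= breakpoint_tolerance:
                clusters[0] = clusters.pop() + clusters[0]
        for cl in clusters:
            groups.append({
                "orientation": orientation,
                "calls": cl,
                "size": len(cl),
                "recurrent": len(cl) >= 2,
            })
    return groups


def summarize_noncanonical(read_records: list[dict]) -> dict:
    """Per-sample noncanonical and palindrome rates.

    ``read_records`` holds one dict per read with keys ``n_complete_copies``,
    ``n_unsuppressed_events`` and ``palindrome_class`` (or None).  Rates are
    reported per copy and per read; with zero copies the per-copy rates are
    absent (None).
    """
    n_reads = len(read_records)
    total_copies = sum(r.get("n_complete_copies", 0) for r in read_records)
    total_events = sum(r.get("n_unsuppressed_events", 0) for r in read_records)
    reads_with_events = sum(1 for r in read_records
                            if r.get("n_unsuppressed_events", 0) > 0)
    candidate_real = sum(1 for r in read_records
                         if r.get("palindrome_class") == "candidate_real")
    summary = {
        "n_reads": n_reads,
        "total_copies": total_copies,
        "noncanonical_events": total_events,
        "reads_with_noncanonical": reads_with_events,
        "candidate_real_palindromes": candidate_real,
        "noncanonical_rate_per_copy": (total_events / total_copies
                                       if total_copies else None),
        "noncanonical_rate_per_read": (reads_with_events / n_reads
                                       if n_reads else None),
        "candidate_real_rate_per_copy": (candidate_real / total_copies
                                         if total_copies else None),
    }
    return summary
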