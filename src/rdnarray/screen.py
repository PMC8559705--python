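"""Screening of reads that represent genuine rDNA array fragments.

Two modes mirror the two library types:

* WGS mode keeps reads carrying a long contiguous stretch of rDNA (>= 40 kb
  by default, touching one end of the read) with a minimum share of sections
  mapping to the coding 45S region — the latter guards against microsatellite
  stretches elsewhere in the genome that resemble the IGS, and the length
  floor removes rDNA-derived pseudogenes outside the array.
* Cas9-enrichment mode keeps fragments whose both termini fall at a guide-RNA
  cut site (within a small tolerance), i.e. fragments excised by two Cas9
  cuts rather than random shearing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .refmodel import ReferenceModel, circular_delta
from .seqio import Read
from .splitmap import ReadAlignmentMap

DEFAULT_MIN_RDNA = 40_000
DEFAULT_MIN_CODING_FRACTION = 0.10
DEFAULT_END_TOLERANCE = 50
MAX_INTERNAL_UNMAPPED = 2  # tolerated mapping dropouts inside a continuous run

# Guide RNA target sequences (protospacer + PAM) used for Cas9 enrichment;
# cut sites default to their exact-match positions in the loaded reference.
CAS9_GUIDE_SEQUENCES = (
    "ATGAACCGAACGCCGGGTTAAGG",
    "AGGACGGTGGCCATGGAAGTCGG",
    "ACCTCCACCAGAGTTTCCTCTGG",
    "TATCCTGAGGGAAACTTCGGAGG",
)


@dataclass(frozen=True)
class ScreenResult:
    read_id: str
    reasons: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    @property
    def verdict(self) -> str:
        return "pass" if not self.reasons else "fail"


def read_sequencing_summary(path: str | Path) -> dict[str, bool]:
    """Platform sequencing-summary TSV -> {read_id: passed QC filtering}."""
    out: dict[str, bool] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["read_id"]] = str(row["passes_filtering"]).upper() in (
                "TRUE", "1", "PASS", "YES")
    return out


def _continuous_runs(amap: ReadAlignmentMap,
                     max_internal_unmapped: int = MAX_INTERNAL_UNMAPPED
                     ) -> list[tuple[int, int]]:
    """Maximal runs of mapped sections tolerating short unmapped interruptions.

    Returns [(start_index, end_index)] over split indices, inclusive, where a
    run may contain internal stretches of at most ``max_internal_unmapped``
    consecutive unmapped sections.
    """
    runs: list[tuple[int, int]] = []
    start = None
    last_mapped = None
    pending_unmapped = 0
    for i, s in enumerate(amap.splits):
        if s.mapped:
            if start is None:
                start = i
            last_mapped = i
            pending_unmapped = 0
        elif start is not None:
            pending_unmapped += 1
            if pending_unmapped > max_internal_unmapped:
                runs.append((start, last_mapped))
                start = None
                pending_unmapped = 0
    if start is not None:
        runs.append((start, last_mapped))
    return runs


def _run_span(amap: ReadAlignmentMap, run: tuple[int, int]) -> int:
    a = amap.splits[run[0]]
    b = amap.splits[run[1]]
    return (b.read_offset + b.length) - a.read_offset


def screen_wgs_read(read: Read, amap: ReadAlignmentMap,
                    qc: dict[str, bool] | None = None,
                    min_rdna: int = DEFAULT_MIN_RDNA,
                    min_coding_fraction: float = DEFAULT_MIN_CODING_FRACTION,
                    ref: ReferenceModel | None = None) -> ScreenResult:
    """WGS screening: QC flag, contiguous rDNA span at a read end, coding share.

    A read passes when (a) it passed platform QC filtering (when a summary is
    supplied), (b) a continuous run of mapped sections touching either read
    end spans at least ``min_rdna`` bases, and (c) sections mapping to the
    coding region make up at least ``min_coding_fraction`` of all sections.
    """
    reasons: list[str] = []
    notes: list[str] = []

    if qc is not None:
        if read.read_id in qc:
            if not qc[read.read_id]:
                reasons.append("qc_filter")
        else:
            notes.append("no_qc_record")

    runs = _continuous_runs(amap)
    end_runs = [r for r in runs
                if r[0] == 0 or r[1] == len(amap.splits) - 1]
    best_span = max((_run_span(amap, r) for r in end_runs), default=0)
    if best_span < min_rdna:
        reasons.append("min_length")

    n_total = len(amap.splits)
    if n_total and ref is not None:
        n_coding = sum(1 for s in amap.mapped_splits
                       if ref.region_of(s.ref_pos) == "coding")
        if n_coding < min_coding_fraction * n_total:
            reasons.append("coding_fraction")
    elif n_total == 0:
        reasons.append("min_length")

    return ScreenResult(read.read_id, tuple(reasons), tuple(notes))


def locate_cut_sites(ref: ReferenceModel,
                     guides: tuple[str, ...] = CAS9_GUIDE_SEQUENCES) -> list[int]:
    """Unit-space cut coordinates: exact matches of guide targets (either strand)."""
    from .kmeralign import revcomp

    sites = []
    for g in guides:
        pos = ref.unit_sequence.find(g)
        if pos < 0:
            pos = ref.unit_sequence.find(revcomp(g))
        if pos >= 0:
            sites.append(pos)
    return sorted(sites)


def screen_cas9_read(read: Read, amap: ReadAlignmentMap, cut_sites: list[int],
                     ref: ReferenceModel,
                     end_tolerance: int = DEFAULT_END_TOLERANCE) -> ScreenResult:
    """Cas9 screening: both read termini must map within tolerance of a cut site."""
    if not cut_sites:
        raise ValueError("cut_sites must be non-empty for Cas9 screening")
    reasons: list[str] = []
    mapped = amap.mapped_splits
    if not mapped:
        return ScreenResult(read.read_id, ("cas9_ends",))
    L = ref.unit_length

    first, last = mapped[0], mapped[-1]
    # unit-space coordinate of the read's physical start / end, extrapolated
    # from the outermost mapped sections (strand-aware)
    if first.strand == "+":
        start_coord = (first.ref_pos - first.read_offset) % L
    else:
        start_coord = (first.ref_pos + first.length + first.read_offset) % L
    tail = len(read) - (last.read_offset + last.length)
    if last.strand == "+":
        end_coord = (last.ref_pos + last.length + tail) % L
    else:
        end_coord = (last.ref_pos - tail) % L

    for coord in (start_coord, end_coord):
        dist = min(abs(circular_delta(coord, c, L)) for c in cut_sites)
        if dist > end_tolerance:
            reasons.append("cas9_ends")
            break
    return ScreenResult(read.read_id, tuple(reasons))


def write_screen_report(results, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tverdict\treasons\tnotes\n")
        for r in results:
            fh.write(f"{r.read_id}\t{r.verdict}\t{','.join(r.reasons) or '.'}\t"
                     f"{','.join(r.notes) or '.'}\n")
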