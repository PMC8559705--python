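"""Split-and-map: fixed-length read sections mapped onto the repeat unit.

A long read is cut into consecutive 300-nt sections; each section is mapped
independently to the single repeat-unit reference.  Plotting each section at
(read offset, mapped unit position) reconstructs the array structure as a dot
plot: a canonical tandem array draws parallel diagonals, and every deviation
(deletion, duplication, inversion) breaks the line.  The per-read collection
of section placements (:class:`ReadAlignmentMap`) is the substrate of all
downstream structure, repeat and methylation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .kmeralign import Hit
from .refmodel import ReferenceModel, circular_delta
from .seqio import Read

DEFAULT_SPLIT_LENGTH = 300
DEFAULT_MIN_TAIL = 150
DEFAULT_GAP_TOLERANCE = 100


@dataclass(frozen=True)
class SplitRead:
    read_id: str
    read_offset: int
    length: int
    sequence: str


@dataclass(frozen=True)
class SplitAlignment:
    """Placement of one section: unit-space start (or None if unmapped)."""

    read_offset: int
    length: int
    ref_pos: int | None
    strand: str | None  # "+" / "-" when mapped
    score: float = 0.0

    @property
    def mapped(self) -> bool:
        return self.ref_pos is not None


@dataclass
class ReadAlignmentMap:
    read_id: str
    read_length: int
    split_length: int
    splits: list[SplitAlignment]
    dominant_strand: str = "+"
    dominant_fraction: float = 1.0

    @property
    def mapped_splits(self) -> list[SplitAlignment]:
        return [s for s in self.splits if s.mapped]

    @property
    def unmapped_count(self) -> int:
        return sum(1 for s in self.splits if not s.mapped)


def split_read(read: Read, split_length: int = DEFAULT_SPLIT_LENGTH,
               min_tail: int = DEFAULT_MIN_TAIL) -> list[SplitRead]:
    """Cut a read into consecutive non-overlapping sections from offset 0.

    The terminal partial section is kept only if it is at least ``min_tail``
    bases long.
    """
    if split_length <= 0:
        raise ValueError("split_length must be positive")
    out = []
    n = len(read.sequence)
    for off in range(0, n, split_length):
        seq = read.sequence[off : off + split_length]
        if len(seq) < split_length and len(seq) < min_tail:
            break
        out.append(SplitRead(read.read_id, off, len(seq), seq))
    return out


def map_splits(splits: Sequence[SplitRead], ref: ReferenceModel, aligner
               ) -> ReadAlignmentMap:
    """Map each section (primary hit only) and assemble the per-read map.

    ``dominant_strand`` is the strand of the majority of mapped sections
    (tie resolves to forward); ``dominant_fraction`` is that majority's share
    of mapped sections.
    """
    if not splits:
        return ReadAlignmentMap("", 0, DEFAULT_SPLIT_LENGTH, [])
    read_id = splits[0].read_id
    split_length = splits[0].length
    try:
        hits: list[Hit | None] = aligner.align_many([s.sequence for s in splits])
    except Exception as exc:  # surface backend failures with read context
        raise RuntimeError(f"aligner backend failed on read {read_id}") from exc

    alns = []
    for s, h in zip(splits, hits):
        if h is None:
            alns.append(SplitAlignment(s.read_offset, s.length, None, None))
        else:
            alns.append(SplitAlignment(s.read_offset, s.length, h.ref_pos,
                                       h.strand, float(h.score)))
    n_fwd = sum(1 for a in alns if a.mapped and a.strand == "+")
    n_rev = sum(1 for a in alns if a.mapped and a.strand == "-")
    if n_fwd + n_rev == 0:
        dominant, fraction = "+", 1.0
    elif n_fwd >= n_rev:
        dominant, fraction = "+", n_fwd / (n_fwd + n_rev)
    else:
        dominant, fraction = "-", n_rev / (n_fwd + n_rev)
    read_length = splits[-1].read_offset + splits[-1].length
    return ReadAlignmentMap(read_id, read_length, split_length, alns,
                            dominant, fraction)


def consecutive_mapped_pairs(amap: ReadAlignmentMap):
    """Yield (a, b) for consecutive mapped sections (unmapped ones skipped)."""
    prev = None
    for s in amap.splits:
        if not s.mapped:
            continue
        if prev is not None:
            yield prev, s
        prev = s


def pair_deviation(a: SplitAlignment, b: SplitAlignment, unit_length: int) -> int:
    """Signed circular deviation of a mapped pair from its expected spacing.

    The expected unit-space displacement between two sections is their read
    offset difference, signed by strand.  Positive deviation means the pair
    skips reference sequence relative to read spacing (a deletion in the
    read); negative means extra read sequence (a duplication/insertion).
    """
    expected = b.read_offset - a.read_offset
    if a.strand == "-":
        # read direction descends in unit space; the coordinate tied to a
        # section's read start is its alignment *end*, which matters when
        # section lengths differ (terminal tail sections)
        delta = -circular_delta(a.ref_pos + a.length, b.ref_pos + b.length,
                                unit_length)
    else:
        delta = circular_delta(a.ref_pos, b.ref_pos, unit_length)
    return delta - expected


def count_reference_gaps(amap: ReadAlignmentMap, ref: ReferenceModel,
                         spacing: int = DEFAULT_SPLIT_LENGTH,
                         tolerance: int = DEFAULT_GAP_TOLERANCE) -> int:
    """Count section pairs whose spacing deviates from expectation.

    For each consecutive pair of mapped same-strand sections, the unit-space
    displacement should equal the read offset difference (circularly, signed
    by strand); pairs deviating by strictly more than ``tolerance`` bases are
    gapped.  Summed over reads, this ranks candidate reference sequences (the
    best reference produces the fewest gaps).
    """
    count = 0
    for a, b in consecutive_mapped_pairs(amap):
        if a.strand != b.strand:
            continue
        if abs(pair_deviation(a, b, ref.unit_length)) > tolerance:
            count += 1
    return count


def write_alignment_table(maps: Sequence[ReadAlignmentMap], path: str | Path) -> None:
    """Per-section placement table (TSV). Coordinates 0-based half-open, unit space."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based, half-open, unit space; UM = unmapped\n")
        fh.write("read_id\tread_offset\tref_pos\tstrand\tscore\n")
        for m in maps:
            for s in m.splits:
                if s.mapped:
                    fh.write(f"{m.read_id}\t{s.read_offset}\t{s.ref_pos}\t"
                             f"{s.strand}\t{s.score:g}\n")
                else:
                    fh.write(f"{m.read_id}\t{s.read_offset}\tUM\t.\t0\n")
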