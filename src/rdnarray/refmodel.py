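"""Repeat-unit reference model and circular coordinate arithmetic.

A tandem rDNA array is analysed against a *single* repeat-unit reference, so
every position lives in "unit space": 0-based, half-open coordinates on the
unit, wrapping at the unit boundary.  The :class:`ReferenceModel` bundles the
unit sequence with the landmarks everything downstream needs: the coding
(45S) interval, the two naturally variable IGS satellite intervals (R repeat
and Butterfly/Long repeat), and the three anchor sections used for repeat
genotyping.

Landmark coordinates are supplied as a BED file naming the three intervals
``coding``, ``r_repeat`` and ``butterfly_long``; anchors are configuration
(defaults follow the human KY962518 layout: 10,000 / 20,000 / 30,000, 500 nt
each).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

REQUIRED_LANDMARKS = ("coding", "r_repeat", "butterfly_long")

DEFAULT_ANCHOR_POSITIONS = (10_000, 20_000, 30_000)
DEFAULT_ANCHOR_LENGTH = 500


class ReferenceError(ValueError):
    """Raised when a reference or its annotation fails validation."""


@dataclass(frozen=True)
class ReferenceModel:
    """A single rDNA repeat unit plus its landmark annotation.

    All coordinates are 0-based, half-open, in unit space.
    """

    unit_sequence: str
    coding_interval: tuple[int, int]
    r_repeat_interval: tuple[int, int]
    butterfly_long_interval: tuple[int, int]
    anchor_positions: tuple[int, ...] = DEFAULT_ANCHOR_POSITIONS
    anchor_length: int = DEFAULT_ANCHOR_LENGTH
    name: str = "unit"

    def __post_init__(self) -> None:
        L = self.unit_length
        intervals = {
            "coding": self.coding_interval,
            "r_repeat": self.r_repeat_interval,
            "butterfly_long": self.butterfly_long_interval,
        }
        for label, (start, end) in intervals.items():
            if label in ("r_repeat", "butterfly_long") and start == end:
                continue  # empty satellite interval is allowed (count 0)
            if not (0 <= start < end <= L):
                raise ReferenceError(
                    f"{label} interval [{start}, {end}) outside unit [0, {L})"
                )
        # coding must not overlap either satellite interval
        for label in ("r_repeat", "butterfly_long"):
            if _overlap(self.coding_interval, intervals[label]):
                raise ReferenceError(f"coding interval overlaps {label}")
        if _overlap(self.r_repeat_interval, self.butterfly_long_interval):
            raise ReferenceError("r_repeat interval overlaps butterfly_long")
        for pos in self.anchor_positions:
            if not (0 <= pos and pos + self.anchor_length <= L):
                raise ReferenceError(
                    f"anchor at {pos} (+{self.anchor_length}) exceeds unit of {L}"
                )

    @property
    def unit_length(self) -> int:
        return len(self.unit_sequence)

    def anchor_sequence(self, i: int) -> str:
        """Sequence of the i-th anchor section (0-based index)."""
        pos = self.anchor_positions[i]
        return self.unit_sequence[pos : pos + self.anchor_length]

    def region_of(self, pos: int) -> str:
        """Classify a unit-space position: coding / r_repeat / butterfly_long / igs_other."""
        p = pos % self.unit_length
        for label, (s, e) in (
            ("coding", self.coding_interval),
            ("r_repeat", self.r_repeat_interval),
            ("butterfly_long", self.butterfly_long_interval),
        ):
            if s <= p < e:
                return label
        return "igs_other"


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    if a[0] == a[1] or b[0] == b[1]:
        return False
    return a[0] < b[1] and b[0] < a[1]


def load_reference(
    fasta_path: str | Path,
    bed_path: str | Path,
    *,
    anchor_positions: Sequence[int] = DEFAULT_ANCHOR_POSITIONS,
    anchor_length: int = DEFAULT_ANCHOR_LENGTH,
) -> ReferenceModel:
    """Load the repeat-unit FASTA and its landmark BED into a ReferenceModel.

    The FASTA must contain exactly one record; the BED must name each of
    ``coding``, ``r_repeat`` and ``butterfly_long`` exactly once.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ReferenceError(
            f"reference FASTA must contain exactly one record, found {len(records)}"
        )
    record = records[0]
    seq = str(record.seq).upper()

    intervals: dict[str, tuple[int, int]] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ReferenceError(f"BED line needs 4 columns: {line!r}")
            name = fields[3]
            if name in intervals:
                raise ReferenceError(f"duplicate landmark {name!r} in BED")
            intervals[name] = (int(fields[1]), int(fields[2]))
    for name in REQUIRED_LANDMARKS:
        if name not in intervals:
            raise ReferenceError(f"annotation is missing landmark {name!r}")

    return ReferenceModel(
        unit_sequence=seq,
        coding_interval=intervals["coding"],
        r_repeat_interval=intervals["r_repeat"],
        butterfly_long_interval=intervals["butterfly_long"],
        anchor_positions=tuple(anchor_positions),
        anchor_length=anchor_length,
        name=record.id,
    )


def circular_delta(ref_pos_a: int, ref_pos_b: int, unit_length: int) -> int:
    """Signed displacement a -> b on a circle of circumference ``unit_length``.

    Returns the representative of (b - a) mod L with minimal absolute value;
    an exact half-circle tie resolves to +L/2.
    """
    if unit_length <= 0:
        raise ValueError("unit_length must be positive")
    d = (ref_pos_b - ref_pos_a) % unit_length
    if d > unit_length / 2:
        d -= unit_length
    return d


def write_reference(ref: ReferenceModel, fasta_path: str | Path, bed_path: str | Path) -> None:
    """Write a ReferenceModel back out as FASTA + landmark BED."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{ref.name}\n")
        seq = ref.unit_sequence
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    with open(bed_path, "w") as fh:
        fh.write("# coordinates: 0-based, half-open, unit space\n")
        for name, (s, e) in (
            ("coding", ref.coding_interval),
            ("r_repeat", ref.r_repeat_interval),
            ("butterfly_long", ref.butterfly_long_interval),
        ):
            fh.write(f"{ref.name}\t{s}\t{e}\t{name}\n")
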