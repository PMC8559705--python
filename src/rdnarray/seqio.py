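"""Lightweight read container and FASTQ I/O (gzip-aware, via Biopython)."""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO


@dataclass
class Read:
    """One sequencing read: id, bases, and per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: np.ndarray | None = None  # Phred scores, same length as sequence

    def __post_init__(self) -> None:
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities, dtype=np.int16)
            if len(self.qualities) != len(self.sequence):
                raise ValueError(
                    f"read {self.read_id}: {len(self.qualities)} qualities for "
                    f"{len(self.sequence)} bases"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_maybe_gz(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[Read]:
    with _open_maybe_gz(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield Read(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=np.asarray(
                    rec.letter_annotations["phred_quality"], dtype=np.int16
                ),
            )


def write_fastq(reads, path: str | Path) -> None:
    with _open_maybe_gz(path, "wt") as fh:
        for read in reads:
            quals = read.qualities
            if quals is None:
                quals = np.full(len(read.sequence), 12, dtype=np.int16)
            qstr = "".join(chr(int(q) + 33) for q in np.clip(quals, 0, 60))
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qstr}\n")
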