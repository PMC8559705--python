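"""Exact k-mer seeding with diagonal voting.

The split-and-map strategy only needs the *start position and strand* of each
short section on the repeat unit, not base-level alignments, so a seed-and-vote
aligner is sufficient: every exact k-mer shared between query and reference
votes for the diagonal ``(ref_pos - query_offset)``, diagonals are clustered
within a small window to absorb indel drift, and the best cluster wins.  The
reference is indexed circularly (the unit is one period of a tandem array), so
sections straddling the unit boundary map seamlessly.

The same machinery locates anchor sections inside read segments for repeat
genotyping (:func:`locate_all`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit encode a sequence; ambiguous bases become -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mers of an encoded sequence as int64 keys, with a validity mask."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    km = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        km = (km << 2) | (c.astype(np.int64) & 3)
        valid &= c >= 0
    return km, valid


class KmerIndex:
    """Sorted exact k-mer index over one sequence.

    With ``circular=True`` the sequence is treated as one period of a tandem
    repeat: k-mers spanning the end/start junction are indexed too and all
    positions are reported modulo the sequence length.
    """

    def __init__(self, seq: str, k: int = 15, *, circular: bool = False,
                 max_hits_per_kmer: int = 32):
        self.k = k
        self.length = len(seq)
        self.circular = circular
        self.max_hits_per_kmer = max_hits_per_kmer
        indexed = seq + seq[: k - 1] if circular else seq
        km, valid = kmer_codes(encode(indexed), k)
        pos = np.nonzero(valid)[0].astype(np.int64)
        km = km[valid]
        order = np.argsort(km, kind="stable")
        self._kmers = km[order]
        self._pos = pos[order]

    def lookup(self, qkmers: np.ndarray, qvalid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Match query k-mers; returns (query_index, reference_position) pairs."""
        lo = np.searchsorted(self._kmers, qkmers, side="left")
        hi = np.searchsorted(self._kmers, qkmers, side="right")
        cnt = hi - lo
        cnt[~qvalid] = 0
        np.minimum(cnt, self.max_hits_per_kmer, out=cnt)
        total = int(cnt.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qidx = np.repeat(np.arange(len(qkmers), dtype=np.int64), cnt)
        excl = np.concatenate(([0], np.cumsum(cnt)[:-1]))
        local = np.arange(total, dtype=np.int64) - np.repeat(excl, cnt)
        return qidx, self._pos[np.repeat(lo, cnt) + local]


@dataclass(frozen=True)
class Hit:
    """One candidate placement of a query: reference start, strand, vote count."""

    ref_pos: int
    strand: str  # "+" or "-"
    score: int


def _cluster_diagonals(diags: np.ndarray, window: int, wrap_length: int | None
                       ) -> list[tuple[int, int]]:
    """Cluster sorted diagonal votes; return [(votes, representative)] best-first.

    The representative is the modal diagonal inside the winning window
    (smallest value on ties).  Clusters are extracted greedily, masking each
    winner's neighbourhood, so returned clusters are mutually distant.
    """
    if len(diags) == 0:
        return []
    d = np.sort(diags)
    if wrap_length is not None:
        low = d[d < window]
        if len(low) and d[-1] >= wrap_length - window:
            d = np.sort(np.concatenate([d, low + wrap_length]))

    out: list[tuple[int, int]] = []
    remaining = d
    while len(remaining):
        ends = np.searchsorted(remaining, remaining + window, side="right")
        votes = ends - np.arange(len(remaining))
        vmax = int(votes.max())
        starts = np.nonzero(votes == vmax)[0]
        best_rep = None
        for s in starts:
            win = remaining[s : s + vmax]
            vals, counts = np.unique(win, return_counts=True)
            rep = int(vals[np.argmax(counts)])
            if wrap_length is not None:
                rep %= wrap_length
            if best_rep is None or rep < best_rep:
                best_rep = rep
        out.append((vmax, int(best_rep)))
        # mask the winner's neighbourhood and look for further clusters
        if wrap_length is not None:
            dist = np.abs((remaining - best_rep + wrap_length // 2) % wrap_length
                          - wrap_length // 2)
        else:
            dist = np.abs(remaining - best_rep)
        remaining = remaining[dist > 2 * window]
    return out


def locate_all(index: KmerIndex, query: str, *, window: int = 30,
               min_votes: int = 8, min_votes_fraction: float = 0.4,
               max_hits: int = 8, both_strands: bool = True) -> list[Hit]:
    """All confident placements of ``query`` on the indexed sequence, best first.

    ``ref_pos`` is the leftmost reference coordinate of the placement (for a
    reverse-strand hit, the coordinate where the query's reverse complement
    starts).  Ties in votes break to the lowest coordinate, then forward
    strand.
    """
    k = index.k
    L = index.length
    wrap = L if index.circular else None
    candidates: list[Hit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        seq = query if strand == "+" else revcomp(query)
        km, valid = kmer_codes(encode(seq), k)
        qidx, pos = index.lookup(km, valid)
        if len(qidx) == 0:
            continue
        diags = pos - qidx
        if wrap is not None:
            diags %= L
        for votes, rep in _cluster_diagonals(diags, window, wrap):
            candidates.append(Hit(ref_pos=rep, strand=strand, score=votes))
    if not candidates:
        return []
    best = max(c.score for c in candidates)
    kept = [c for c in candidates
            if c.score >= min_votes and c.score >= min_votes_fraction * best]
    kept.sort(key=lambda h: (-h.score, h.ref_pos, h.strand))
    return kept[:max_hits]


class BuiltinAligner:
    """Built-in section aligner: exact k-mer seeds + diagonal vote, both strands.

    Deterministic and seed-free; the pluggable backend used by default for the
    split-and-map pipeline.
    """

    name = "builtin"

    def __init__(self, ref, *, k: int = 15, window: int = 30, min_votes: int = 8):
        self.ref = ref
        self.k = k
        self.window = window
        self.min_votes = min_votes
        self.index = KmerIndex(ref.unit_sequence, k, circular=True)

    def align_one(self, seq: str) -> Hit | None:
        hits = locate_all(self.index, seq, window=self.window,
                          min_votes=self.min_votes, max_hits=1)
        return hits[0] if hits else None

    def align_many(self, seqs: list[str]) -> list[Hit | None]:
        return [self.align_one(s) for s in seqs]


class Minimap2Aligner:
    """External backend driving the ``minimap2`` binary in one batch call.

    Used for cross-checking the built-in aligner; maps against the *linear*
    unit sequence, so sections straddling the unit boundary may be clipped.
    """

    name = "minimap2"

    def __init__(self, ref, *, preset: str = "map-ont"):
        self.ref = ref
        self.preset = preset

    def align_many(self, seqs: list[str]) -> list[Hit | None]:
        import subprocess
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            ref_fa = tmp / "ref.fa"
            ref_fa.write_text(f">{self.ref.name}\n{self.ref.unit_sequence}\n")
            qry_fa = tmp / "qry.fa"
            with open(qry_fa, "w") as fh:
                for i, s in enumerate(seqs):
                    fh.write(f">q{i}\n{s}\n")
            proc = subprocess.run(
                ["minimap2", "-x", self.preset, "--secondary=no", "-t", "1",
                 str(ref_fa), str(qry_fa)],
                capture_output=True, text=True, check=True,
            )
        results: list[Hit | None] = [None] * len(seqs)
        best_score = [-1] * len(seqs)
        for line in proc.stdout.splitlines():
            f = line.split("\t")
            i = int(f[0][1:])
            strand = f[4]
            ref_start, ref_end = int(f[7]), int(f[8])
            q_start, q_end = int(f[2]), int(f[3])
            score = int(f[9])  # matching bases
            if strand == "+":
                pos = ref_start - q_start  # extrapolate clipped query start
            else:
                qlen = int(f[1])
                pos = ref_start - (qlen - q_end)
            pos %= self.ref.unit_length
            if score > best_score[i] or (score == best_score[i]
                                         and pos < results[i].ref_pos):
                results[i] = Hit(ref_pos=pos, strand=strand, score=score)
                best_score[i] = score
        return results


def make_aligner(ref, backend: str = "builtin", **kwargs):
    """Aligner factory keyed by backend name (``builtin`` or ``minimap2``)."""
    if backend == "builtin":
        return BuiltinAligner(ref, **kwargs)
    if backend == "minimap2":
        return Minimap2Aligner(ref, **kwargs)
    raise ValueError(f"unknown aligner backend {backend!r}")
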