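"""CpG methylation profiling of rDNA copies from per-CpG posteriors.

Input is a per-read table of modified-base calls: (read id, read position,
posterior probability that the CpG is methylated).  Two summary metrics are
supported throughout: the *average* metric (mean of posteriors — an expected
methylated fraction) and the *threshold* metric (share of CpGs with
posterior >= 0.8).

Per copy, the mean posterior over the coding 45S sub-interval classifies the
copy all-or-none: strictly above the 0.1 border = methylated, otherwise
unmethylated (unmethylated copies are the presumed transcriptionally active
ones).  IGS methylation is computed with the Butterfly/Long satellite
excluded (few CpGs, variable length).  Sample-level statistics cover the
45S-IGS correlation on the strongly methylated stratum, adjacency vs
randomized controls, the adjacent-pair switch rate, depth-ratio copy-number
estimation, and the constant-active-copy analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .repeats import compare_adjacent_vs_random
from .structure import CopySegment

DEFAULT_BIN_SIZE = 200
DEFAULT_POSTERIOR_THRESHOLD = 0.8
DEFAULT_METHYL_BORDER = 0.1
DEFAULT_STRONG_CUTOFF = 0.3
DEFAULT_GENOME_SIZE = 6.27e9  # diploid human genome, bases


@dataclass(frozen=True)
class MethylCall:
    read_id: str
    position: int     # read space, 0-based
    posterior: float  # P(methylated)


@dataclass
class MethylationProfile:
    """200-nt binned methylation track of one read (both metrics)."""

    read_id: str
    bin_size: int
    bin_start: np.ndarray    # read-space start of each occupied bin
    n_cpg: np.ndarray
    avg_freq: np.ndarray     # mean posterior per bin
    thresh_freq: np.ndarray  # share of CpGs with posterior >= threshold


@dataclass
class CopyMethylStatus:
    read_id: str
    copy_index: int
    mean_45s: float
    n_cpg: int
    methyl_class: str                 # "methylated" / "unmethylated"
    igs_methylation: float | None = None


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    rdna_bases: int
    total_bases: int
    genome_size: float
    unit_length: int

    @property
    def rdna_fraction(self) -> float:
        return self.rdna_bases / self.total_bases

    @property
    def copies_per_cell(self) -> float:
        return self.rdna_fraction * self.genome_size / self.unit_length


def read_methylation_tsv(path: str | Path) -> dict[str, list[MethylCall]]:
    """Canonical call table (read_id, position, posterior) -> calls per read."""
    out: dict[str, list[MethylCall]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            p = float(row["posterior"])
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"posterior {p} outside [0, 1]")
            call = MethylCall(row["read_id"], int(row["position"]), p)
            out.setdefault(call.read_id, []).append(call)
    for calls in out.values():
        calls.sort(key=lambda c: c.position)
    return out


def write_methylation_tsv(calls: list[MethylCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tposition\tposterior\n")
        for c in calls:
            fh.write(f"{c.read_id}\t{c.position}\t{c.posterior:.4f}\n")


def read_calls_from_bam(path: str | Path) -> dict[str, list[MethylCall]]:
    """Optional adapter: MM/ML-tagged BAM/SAM -> the same per-read call lists."""
    import pysam

    out: dict[str, list[MethylCall]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.modified_bases is None:
                continue
            for (_base, _strand, _mod), sites in rec.modified_bases.items():
                calls = out.setdefault(rec.query_name, [])
                for pos, qual in sites:
                    calls.append(MethylCall(rec.query_name, pos, (qual + 0.5) / 256))
    for calls in out.values():
        calls.sort(key=lambda c: c.position)
    return out


def bin_methylation(calls: list[MethylCall], read_length: int,
                    bin_size: int = DEFAULT_BIN_SIZE,
                    threshold: float = DEFAULT_POSTERIOR_THRESHOLD
                    ) -> MethylationProfile:
    """Bin per-CpG posteriors along the read; bins without CpGs are omitted."""
    read_id = calls[0].read_id if calls else ""
    pos = np.array([c.position for c in calls], dtype=np.int64)
    post = np.array([c.posterior for c in calls], dtype=float)
    if np.any((post < 0) | (post > 1)):
        raise ValueError("posterior outside [0, 1]")
    if np.any((pos < 0) | (pos >= read_length)):
        raise ValueError("call position outside the read")
    bins = pos // bin_size
    occupied = np.unique(bins)
    n_cpg = np.array([(bins == b).sum() for b in occupied])
    avg = np.array([post[bins == b].mean() for b in occupied])
    thr = np.array([(post[bins == b] >= threshold).mean() for b in occupied])
    return MethylationProfile(read_id, bin_size, occupied * bin_size,
                              n_cpg, avg, thr)


def _mean_posterior_in(calls: list[MethylCall],
                       intervals) -> tuple[float | None, int]:
    sel = [c.posterior for c in calls
           if any(a <= c.position < b for a, b in intervals)]
    if not sel:
        return None, 0
    return float(np.mean(sel)), len(sel)


def copy_methylation(segment: CopySegment, calls: list[MethylCall],
                     border: float = DEFAULT_METHYL_BORDER
                     ) -> CopyMethylStatus | None:
    """All-or-none 45S classification of one copy.

    The copy's score is the mean posterior over CpGs inside its coding
    sub-interval; strictly above the border = methylated.  Returns None when
    the segment has no located coding interval or no CpG calls inside it.
    """
    if segment.coding_read_interval is None:
        return None
    mean, n = _mean_posterior_in(calls, [segment.coding_read_interval])
    if mean is None:
        return None
    cls = "methylated" if mean > border else "unmethylated"
    return CopyMethylStatus(segment.read_id, segment.index, mean, n, cls)


def igs_methylation(segment: CopySegment, calls: list[MethylCall]
                    ) -> float | None:
    """Mean posterior over the copy's IGS, Butterfly/Long region excluded."""
    if not segment.igs_read_intervals:
        return None
    mean, _ = _mean_posterior_in(calls, segment.igs_read_intervals)
    return mean


def correlate_45s_igs(statuses: list[CopyMethylStatus],
                      strong_cutoff: float = DEFAULT_STRONG_CUTOFF,
                      min_stratum: int = 10) -> dict:
    """Pearson correlation of 45S vs flanking IGS methylation.

    Restricted to strongly methylated copies (mean 45S strictly above the
    cutoff) — below it the 45S score carries no gradation to correlate.
    """
    pairs = [(s.mean_45s, s.igs_methylation) for s in statuses
             if s.mean_45s > strong_cutoff and s.igs_methylation is not None]
    if len(pairs) < min_stratum:
        return {"r": None, "p": None, "n": len(pairs),
                "note": "insufficient strongly methylated copies"}
    x = np.array([a for a, _ in pairs])
    y = np.array([b for _, b in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": None, "p": None, "n": len(pairs), "note": "zero variance"}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(pairs), "note": ""}


def _group_by_read(statuses: list[CopyMethylStatus]
                   ) -> dict[str, list[CopyMethylStatus]]:
    by_read: dict[str, list[CopyMethylStatus]] = {}
    for s in statuses:
        by_read.setdefault(s.read_id, []).append(s)
    for members in by_read.values():
        members.sort(key=lambda s: s.copy_index)
    return by_read


def methylation_adjacency(statuses: list[CopyMethylStatus], n_random: int,
                          seed: int) -> dict:
    """Adjacent |delta mean 45S| within reads vs a seeded random-pair control."""
    by_read = _group_by_read(statuses)
    adjacent: list[float] = []
    for members in by_read.values():
        for a, b in zip(members, members[1:]):
            if b.copy_index == a.copy_index + 1:
                adjacent.append(abs(a.mean_45s - b.mean_45s))
    if not adjacent:
        return {"adjacent": [], "control": [], "statistic": None, "p": None,
                "note": "no reads with >= 2 copies"}
    pool = np.array([s.mean_45s for s in statuses])
    rng = np.random.default_rng(seed)
    control = []
    for _ in range(n_random):
        i, j = rng.choice(len(pool), size=2, replace=False)
        control.append(abs(float(pool[i]) - float(pool[j])))
    stat, p = compare_adjacent_vs_random(adjacent, control)
    return {"adjacent": adjacent, "control": control, "statistic": stat,
            "p": p, "note": ""}


def methylation_switch_rate(statuses: list[CopyMethylStatus]) -> dict:
    """Share of adjacent copy pairs with different all-or-none class.

    Also reports the implied mean run length (1 / rate) of same-class
    stretches.  With zero eligible pairs the rate is undefined (None).
    """
    by_read = _group_by_read(statuses)
    switches = 0
    pairs = 0
    for members in by_read.values():
        for a, b in zip(members, members[1:]):
            if b.copy_index != a.copy_index + 1:
                continue
            pairs += 1
            if a.methyl_class != b.methyl_class:
                switches += 1
    if pairs == 0:
        return {"rate": None, "n_pairs": 0, "mean_run_length": None}
    rate = switches / pairs
    return {"rate": rate, "n_pairs": pairs,
            "mean_run_length": (1.0 / rate) if rate > 0 else float("inf")}


def estimate_copy_number(rdna_bases: int, total_bases: int, unit_length: int,
                         genome_size: float = DEFAULT_GENOME_SIZE,
                         sample_id: str = "sample") -> CopyNumberEstimate:
    """Copies per cell from the base-weighted rDNA share of sequencing output.

    copies = (rDNA bases / total bases) x genome size / unit length.
    """
    if unit_length <= 0:
        raise ValueError("unit_length must be positive")
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    if rdna_bases > total_bases:
        raise ValueError("rdna_bases cannot exceed total_bases")
    return CopyNumberEstimate(sample_id, rdna_bases, total_bases,
                              genome_size, unit_length)


def active_copy_analysis(samples: list[tuple[float, float]]) -> dict:
    """Constant-active-copy test across samples.

    ``samples`` holds (copies per cell N, unmethylated proportion p) pairs.
    Reports Pearson r for (N, p) and for (N, N*p), and the least-squares fit
    of p = A / N — A is the implied constant number of active (unmethylated)
    copies per cell.
    """
    if len(samples) < 5:
        raise ValueError("need >= 5 samples")
    n = np.array([s[0] for s in samples], dtype=float)
    p = np.array([s[1] for s in samples], dtype=float)
    if np.ptp(n) == 0:
        return {"A": None, "r_proportion": None, "r_active": None,
                "note": "no variance in copy number"}
    r_prop, p_prop = stats.pearsonr(n, p)
    active = n * p
    if np.ptp(active) == 0:
        r_act, p_act = 0.0, 1.0
    else:
        r_act, p_act = stats.pearsonr(n, active)
    # least squares of p = A/N  <=>  regression of p on 1/N through origin
    x = 1.0 / n
    A = float(np.dot(x, p) / np.dot(x, x))
    return {"A": A, "r_proportion": float(r_prop), "p_proportion": float(p_prop),
            "r_active": float(r_act), "p_active": float(p_act), "note": ""}


def correlate_r_repeat_methylation(samples: dict[str, tuple[list, list]],
                                   min_copies: int = 10,
                                   alpha: float = 0.05) -> list[dict]:
    """Per-sample Spearman rho between R-repeat size and 45S methylation.

    ``samples`` maps sample id to paired per-copy lists (R-repeat values,
    45S methylation means).  Benjamini-Hochberg FDR is applied across
    samples; samples with too few paired copies or a constant R value are
    skipped (rho undefined).
    """
    from statsmodels.stats.multitest import multipletests

    rows: list[dict] = []
    pvals: list[float] = []
    for sample_id, (r_values, meth_values) in samples.items():
        pairs = [(r, m) for r, m in zip(r_values, meth_values)
                 if r is not None and m is not None]
        if len(pairs) < min_copies:
            rows.append({"sample": sample_id, "rho": None, "p": None,
                         "skipped": True, "note": "too few paired copies"})
            continue
        x = np.array([a for a, _ in pairs], dtype=float)
        y = np.array([b for _, b in pairs], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"sample": sample_id, "rho": None, "p": None,
                         "skipped": True, "note": "constant values"})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"sample": sample_id, "rho": float(rho), "p": float(p),
                     "skipped": False, "note": ""})
        pvals.append(float(p))
    if pvals:
        rejected, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        it = iter(zip(rejected, qvals))
        for row in rows:
            if not row["skipped"]:
                rej, q = next(it)
                row["fdr_significant"] = bool(rej)
                row["q"] = float(q)
    return rows
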