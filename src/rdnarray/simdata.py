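"""Synthetic tandem rDNA arrays, Nanopore-like reads and methylation calls.

Every pipeline stage is testable at desk scale against planted truth:

* a synthetic repeat unit with a coding region, embedded guide-target sites,
  and internally repetitive R (~680 bp) and Butterfly/Long (~4,500 bp)
  satellite blocks whose per-copy counts vary between array copies;
* multi-unit array reads with unit-level repeat variation (optionally
  correlated between adjacent copies, emulating gene-conversion
  homogenization), planted structural events, and a substitution/indel error
  model with coordinate-tracked truth;
* template-switch artifact reads (the second, complementary strand appended
  with random termination and a quality drop) and genuine palindromes with
  random read framing;
* bimodal per-CpG methylation posteriors (unmethylated copies ~Beta(1,20),
  methylated ~Beta(8,8)) with an always-methylated IGS, plus whole-sample
  scenarios with constant active copies across varying totals.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .kmeralign import revcomp
from .methylation import MethylCall
from .refmodel import ReferenceModel
from .seqio import Read

R_UNIT_LENGTH = 680
BL_UNIT_LENGTH = 4500
R_CORE_LENGTH = 85      # internal period of the R satellite
BL_CORE_LENGTH = 500    # internal period of the Butterfly/Long satellite
UNIT_DIVERGENCE = 0.07  # substitution divergence between tandem satellite units

CODING_LENGTH = 12_000
PRE_LENGTH = 13_000     # backbone before the R block (contains the coding region)
MID_LENGTH = 8_000      # backbone between the R block and the Butterfly/Long block

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE_OF[ord(_b)] = _i

# guide targets planted into the synthetic coding region so that Cas9-mode
# screening works identically on synthetic and real references
from .screen import CAS9_GUIDE_SEQUENCES

GUIDE_PLANT_START = 9_400
GUIDE_PLANT_STRIDE = 40


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    codes = _CODE_OF[np.frombuffer(seq.encode(), np.uint8)].astype(np.int64)
    hit = rng.random(len(codes)) < rate
    codes[hit] = (codes[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
    return _BASES[codes].tobytes().decode("ascii")


@dataclass
class ErrorModel:
    """Per-base Nanopore-like error rates."""

    substitution: float = 0.03
    insertion: float = 0.01
    deletion: float = 0.01

    def __post_init__(self) -> None:
        for r in (self.substitution, self.insertion, self.deletion):
            if not (0.0 <= r <= 0.2):
                raise ValueError("error rates must lie in [0, 0.2]")

    @property
    def total(self) -> float:
        return self.substitution + self.insertion + self.deletion


ERROR_FREE = ErrorModel(0.0, 0.0, 0.0)


@dataclass
class CopySpec:
    """Planted composition of one array copy."""

    r_count: int
    bl_count: int
    events: list[tuple[str, int, int]] = field(default_factory=list)
    meth_state: str = "M"  # "U" unmethylated / "M" methylated (45S)


@dataclass
class ArraySpec:
    """Planted composition of one simulated array (one read's worth)."""

    copies: list[CopySpec]
    seed: int = 0


@dataclass
class ReadTruth:
    """Planted structure of one simulated read, in final read coordinates."""

    read_id: str
    read_length: int
    is_rdna: bool = True
    copy_boundaries: list[int] = field(default_factory=list)  # origin crossings
    copies: list[dict] = field(default_factory=list)
    inversion_offset: int | None = None
    n_complete_copies: int = 0

    def to_json(self) -> dict:
        return asdict(self)


class SyntheticReference(ReferenceModel):
    """A synthetic repeat unit that also knows how to build variant copies."""

    # populated by make_synthetic_reference
    parts: dict

    def r_units_for(self, count: int) -> list[str]:
        base = self.parts["r_units"]
        out = list(base[:count])
        rng = np.random.default_rng(self.parts["extra_seed"])
        while len(out) < count:
            out.append(_mutate(self.parts["r_template"], UNIT_DIVERGENCE, rng))
        return out

    def bl_units_for(self, count: int) -> list[str]:
        base = self.parts["bl_units"]
        out = list(base[:count])
        rng = np.random.default_rng(self.parts["extra_seed"] + 1)
        while len(out) < count:
            out.append(_mutate(self.parts["bl_template"], UNIT_DIVERGENCE, rng))
        return out


def make_synthetic_reference(n_r: int = 3, n_bl: int = 2,
                             backbone_length: int = 30_000,
                             seed: int = 0) -> SyntheticReference:
    """Random repeat unit with embedded satellite blocks and guide sites.

    Layout (unit space): coding region [0, 12000) inside a backbone prefix,
    then ``n_r`` R units of 680 bp, a backbone spacer, ``n_bl``
    Butterfly/Long units of 4500 bp, and a backbone suffix.  Satellite units
    are internally repetitive (85 bp / 500 bp cores) and diverge ~7% between
    tandem copies.  Anchors are placed in unique sequence: inside the coding
    region, between the two satellite blocks, and after the Butterfly/Long
    block.  unit_length = backbone_length + 680*n_r + 4500*n_bl.
    """
    if n_r < 0 or n_bl < 0:
        raise ValueError("satellite unit counts must be non-negative")
    if backbone_length < PRE_LENGTH + MID_LENGTH + 2_000:
        raise ValueError(f"backbone_length must be >= {PRE_LENGTH + MID_LENGTH + 2000}")
    rng = np.random.default_rng(seed)

    backbone = _random_seq(rng, backbone_length)
    pre = backbone[:PRE_LENGTH]
    mid = backbone[PRE_LENGTH: PRE_LENGTH + MID_LENGTH]
    post = backbone[PRE_LENGTH + MID_LENGTH:]

    # plant guide targets in the coding region
    pre_list = list(pre)
    for i, g in enumerate(CAS9_GUIDE_SEQUENCES):
        start = GUIDE_PLANT_START + i * GUIDE_PLANT_STRIDE
        pre_list[start: start + len(g)] = g
    pre = "".join(pre_list)

    r_core = _random_seq(rng, R_CORE_LENGTH)
    r_template = (r_core * (R_UNIT_LENGTH // R_CORE_LENGTH + 1))[:R_UNIT_LENGTH]
    r_units = [_mutate(r_template, UNIT_DIVERGENCE, rng) for _ in range(n_r)]
    bl_core = _random_seq(rng, BL_CORE_LENGTH)
    bl_template = (bl_core * (BL_UNIT_LENGTH // BL_CORE_LENGTH + 1))[:BL_UNIT_LENGTH]
    bl_units = [_mutate(bl_template, UNIT_DIVERGENCE, rng) for _ in range(n_bl)]

    unit = pre + "".join(r_units) + mid + "".join(bl_units) + post
    r_start = PRE_LENGTH
    r_end = r_start + R_UNIT_LENGTH * n_r
    bl_start = r_end + MID_LENGTH
    bl_end = bl_start + BL_UNIT_LENGTH * n_bl
    L = len(unit)

    a1 = CODING_LENGTH - 2_000
    a2 = (r_end + bl_start) // 2 - 250
    a3 = (bl_end + L) // 2 - 250

    ref = SyntheticReference(
        unit_sequence=unit,
        coding_interval=(0, CODING_LENGTH),
        r_repeat_interval=(r_start, r_end),
        butterfly_long_interval=(bl_start, bl_end),
        anchor_positions=(a1, a2, a3),
        anchor_length=500,
        name=f"synthetic_unit_seed{seed}",
    )
    object.__setattr__(ref, "parts", {
        "pre": pre, "mid": mid, "post": post,
        "r_units": r_units, "bl_units": bl_units,
        "r_template": r_template, "bl_template": bl_template,
        "n_r": n_r, "n_bl": n_bl,
        "extra_seed": int(rng.integers(0, 2**31 - 1)),
    })
    return ref


def build_copy(ref: SyntheticReference, spec: CopySpec) -> tuple[str, dict]:
    """Assemble one copy's sequence from its spec; returns (sequence, truth).

    Structural events are restricted to the coding region so that they never
    interfere with the satellite blocks; an event larger than the coding
    region is rejected.
    """
    a1, a2, _ = ref.anchor_positions
    seq = ref.parts["pre"]
    coding_len = CODING_LENGTH
    anchor_r_shift = 0  # event length change landing between anchors 1 and 2
    for etype, pos, size in spec.events:
        if size <= 0 or pos < 0 or pos + size > CODING_LENGTH:
            raise ValueError(f"event {etype}@{pos}+{size} outside the coding region")
        if etype == "deletion":
            seq = seq[:pos] + seq[pos + size:]
            coding_len -= size
            if pos >= a1 + ref.anchor_length:
                anchor_r_shift -= size
        elif etype == "duplication":
            seq = seq[:pos + size] + seq[pos:]
            coding_len += size
            if pos >= a1 + ref.anchor_length:
                anchor_r_shift += size
        else:
            raise ValueError(f"unknown event type {etype!r}")

    seq += "".join(ref.r_units_for(spec.r_count))
    seq += ref.parts["mid"]
    seq += "".join(ref.bl_units_for(spec.bl_count))
    seq += ref.parts["post"]

    truth = {
        "r_count": spec.r_count,
        "bl_count": spec.bl_count,
        "delta_r": (spec.r_count - ref.parts["n_r"]) * R_UNIT_LENGTH + anchor_r_shift,
        "delta_bl": (spec.bl_count - ref.parts["n_bl"]) * BL_UNIT_LENGTH,
        "events": list(spec.events),
        "meth_state": spec.meth_state,
        "copy_length": len(seq),
        "coding_length": coding_len,
    }
    return seq, truth


def apply_errors(seq: str, errors: ErrorModel, rng: np.random.Generator
                 ) -> tuple[str, np.ndarray]:
    """Apply substitution/insertion/deletion noise to a sequence.

    Returns the noisy sequence and a coordinate map ``cum`` with
    ``cum[p]`` = output coordinate of clean position ``p`` (length n+1).
    """
    codes = _CODE_OF[np.frombuffer(seq.encode(), np.uint8)].astype(np.int64)
    n = len(codes)
    if errors.total == 0:
        return seq, np.arange(n + 1, dtype=np.int64)
    deleted = rng.random(n) < errors.deletion
    sub = rng.random(n) < errors.substitution
    ins = rng.random(n) < errors.insertion
    counts = (~deleted).astype(np.int64) + ins
    cum = np.concatenate(([0], np.cumsum(counts)))
    out = np.empty(int(cum[-1]), dtype=np.int64)
    ins_pos = cum[:-1][ins]
    out[ins_pos] = rng.integers(0, 4, int(ins.sum()))
    keep = ~deleted
    kept_pos = cum[:-1][keep] + ins[keep]
    vals = codes.copy()
    vals[sub] = (vals[sub] + rng.integers(1, 4, int(sub.sum()))) % 4
    out[kept_pos] = vals[keep]
    return _BASES[out].tobytes().decode("ascii"), cum


def _quality_track(n: int, rng: np.random.Generator, mean: int = 12) -> np.ndarray:
    return np.clip(mean + rng.integers(-2, 3, n), 2, 60).astype(np.int16)


def copy_length(ref: SyntheticReference, spec: CopySpec) -> int:
    """Clean length of one copy without assembling its sequence."""
    n = ref.unit_length
    n += (spec.r_count - ref.parts["n_r"]) * R_UNIT_LENGTH
    n += (spec.bl_count - ref.parts["n_bl"]) * BL_UNIT_LENGTH
    for etype, _pos, size in spec.events:
        n += size if etype == "duplication" else -size
    return n


def simulate_array_read(ref: SyntheticReference, spec: ArraySpec,
                        start_phase: int = 0, n_units: int | None = None,
                        errors: ErrorModel = ERROR_FREE, seed: int = 0,
                        read_id: str = "simread",
                        clip_length: int | None = None) -> tuple[Read, ReadTruth]:
    """One multi-unit array read with planted truth.

    Copies from ``spec`` (the first ``n_units``) are concatenated and the
    first ``start_phase`` bases are dropped, so the read begins mid-copy when
    a phase is given; ``clip_length`` optionally truncates the clean read
    (e.g. at a Cas9 cut inside the last copy).  The error model is applied
    last; all truth coordinates (copy boundaries, coding intervals) are
    reported in final read space.  A copy is complete when its whole span
    lies inside the read.
    """
    if n_units is None:
        n_units = len(spec.copies)
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    copies = [spec.copies[i % len(spec.copies)] for i in range(n_units)]
    rng = np.random.default_rng(seed)

    seqs, truths = [], []
    for c in copies:
        s, t = build_copy(ref, c)
        seqs.append(s)
        truths.append(t)
    clean = "".join(seqs)[start_phase:]
    if clip_length is not None:
        clean = clean[:clip_length]
    total_clean = len(clean)
    boundaries_clean = []
    acc = 0
    coding_clean = []
    for t in truths:
        boundaries_clean.append(acc - start_phase)
        coding_clean.append((acc - start_phase, acc - start_phase + t["coding_length"]))
        acc += t["copy_length"]

    noisy, cum = apply_errors(clean, errors, rng)

    def remap(p: int) -> int:
        return int(cum[min(max(p, 0), total_clean)])

    boundaries = []
    kept_truths = []
    for i, b in enumerate(boundaries_clean):
        if b >= total_clean:
            continue
        if 0 < b:
            boundaries.append(remap(b))
        end_clean = b + truths[i]["copy_length"]
        truths[i]["read_coding_interval"] = (
            remap(coding_clean[i][0]), remap(coding_clean[i][1]))
        truths[i]["complete"] = bool(b >= 0 and end_clean <= total_clean)
        truths[i]["read_interval"] = (remap(b), remap(end_clean))
        kept_truths.append(truths[i])
    truths = kept_truths

    qual = _quality_track(len(noisy), rng)
    read = Read(read_id, noisy, qual)
    truth = ReadTruth(
        read_id=read_id, read_length=len(noisy), is_rdna=True,
        copy_boundaries=boundaries, copies=truths,
        n_complete_copies=sum(1 for t in truths if t["complete"]),
    )
    return read, truth


def simulate_template_switch(read: Read, termination: float | str = "uniform",
                             quality_drop: int = 7, seed: int = 0
                             ) -> tuple[Read, ReadTruth]:
    """Fake-palindrome artifact: append the restarted complementary strand.

    After finishing the first strand the sequencer continues onto the second
    (complementary) strand, which terminates at a random point.  The
    appended part is the reverse complement of the read's tail, so the
    inversion point sits at the original read end: relative position
    1/(1+f) >= 0.5 for any termination fraction f in (0, 1].  Second-strand
    qualities are reduced by ``quality_drop``.
    """
    if len(read) == 0:
        raise ValueError("read must be non-empty")
    rng = np.random.default_rng(seed)
    if termination == "uniform":
        f = float(rng.uniform(0.05, 1.0))
    else:
        f = float(termination)
    if not (0 < f <= 1):
        raise ValueError("termination fraction must lie in (0, 1]")
    m = max(1, int(round(f * len(read))))
    second = revcomp(read.sequence[len(read) - m:])
    q1 = read.qualities if read.qualities is not None else _quality_track(len(read), rng)
    q2 = np.clip(q1[len(read) - m:][::-1] - quality_drop, 2, 60)
    artifact = Read(read.read_id + "_ts", read.sequence + second,
                    np.concatenate([q1, q2]))
    truth = ReadTruth(
        read_id=artifact.read_id, read_length=len(artifact),
        inversion_offset=len(read),
    )
    return artifact, truth


def simulate_true_palindrome(ref: SyntheticReference, n_units: int = 1,
                             read_length: int | None = None, seed: int = 0,
                             errors: ErrorModel = ERROR_FREE,
                             frame: float | str = "uniform",
                             read_id: str = "palindrome") -> tuple[Read, ReadTruth]:
    """A genuine genomic palindrome read with random framing.

    The molecule is an arm of ``n_units`` reference copies followed by its
    reverse complement; the read is a window over the molecule that covers
    the fold point, so the inversion's relative position lands on either
    side of 0.5.  ``frame`` places the window: drawn uniformly by default,
    or a fraction in [0, 1] for a stratified design (0 puts the fold near
    the read end, 1 near the read start).
    """
    rng = np.random.default_rng(seed)
    arm_spec = CopySpec(r_count=ref.parts["n_r"], bl_count=ref.parts["n_bl"])
    arm = "".join(build_copy(ref, arm_spec)[0] for _ in range(n_units))
    molecule = arm + revcomp(arm)
    junction = len(arm)
    if read_length is None:
        read_length = len(arm)
    margin = max(2000, read_length // 10)
    lo = max(0, junction - read_length + margin)
    hi = junction - margin
    if frame == "uniform":
        start = int(rng.integers(lo, hi + 1))
    else:
        start = lo + int(round(float(frame) * (hi - lo)))
    clean = molecule[start: start + read_length]
    noisy, cum = apply_errors(clean, errors, rng)
    inv = int(cum[junction - start])
    read = Read(read_id, noisy, _quality_track(len(noisy), rng))
    truth = ReadTruth(read_id=read_id, read_length=len(noisy),
                      inversion_offset=inv)
    return read, truth


DEFAULT_UNMETH_BETA = (1.0, 20.0)
DEFAULT_METH_BETA = (8.0, 8.0)


def simulate_methylation_calls(truth: ReadTruth, cpg_density: float = 0.02,
                               unmeth_beta: tuple[float, float] = DEFAULT_UNMETH_BETA,
                               meth_beta: tuple[float, float] = DEFAULT_METH_BETA,
                               seed: int = 0) -> list[MethylCall]:
    """Bimodal per-CpG posteriors over a simulated read.

    CpG sites are placed at the given density; sites inside a copy's coding
    interval draw from that copy's state Beta, all other (IGS) sites draw
    from the methylated Beta — the spacer is heavily methylated regardless
    of the 45S state.
    """
    if cpg_density <= 0:
        raise ValueError("cpg_density must be positive")
    rng = np.random.default_rng(seed)
    n_sites = int(truth.read_length * cpg_density)
    positions = np.sort(rng.choice(truth.read_length, size=n_sites, replace=False))
    coding = [(c["read_coding_interval"], c["meth_state"])
              for c in truth.copies if "read_coding_interval" in c]
    calls: list[MethylCall] = []
    for p in positions:
        state = "M"
        for (a, b), s in coding:
            if a <= p < b:
                state = s
                break
        a_, b_ = unmeth_beta if state == "U" else meth_beta
        calls.append(MethylCall(truth.read_id, int(p), float(rng.beta(a_, b_))))
    return calls


def markov_methylation_states(n: int, p_unmeth: float, switch_rate: float,
                              rng: np.random.Generator) -> list[str]:
    """Stationary two-state chain of 45S states with a target pair-switch rate.

    Transition intensities are chosen so that the stationary distribution is
    (p_unmeth, 1 - p_unmeth) and the probability that an adjacent pair
    differs equals ``switch_rate`` (capped where infeasible).
    """
    pu = min(max(p_unmeth, 1e-9), 1 - 1e-9)
    pm = 1 - pu
    c = switch_rate / (2 * pu * pm)
    p_um = min(c * pm, 1.0)   # P(U -> M)
    p_mu = min(c * pu, 1.0)   # P(M -> U)
    states = []
    s = "U" if rng.random() < pu else "M"
    for _ in range(n):
        states.append(s)
        if s == "U":
            s = "M" if rng.random() < p_um else "U"
        else:
            s = "U" if rng.random() < p_mu else "M"
    return states


@dataclass
class SampleScenario:
    """Full configuration of one simulated sample."""

    mode: str = "wgs"                       # "wgs" or "cas9"
    n_rdna_reads: int = 20
    units_per_read: tuple[int, int] = (2, 3)
    start_phase_fraction: tuple[float, float] = (0.0, 0.9)
    n_background: int = 0
    background_length: tuple[int, int] = (5_000, 30_000)
    n_decoys: int = 0
    decoy_span: tuple[int, int] = (5_000, 30_000)
    r_count_choices: tuple[int, ...] = (0, 1, 2, 3, 4)
    r_count_probs: tuple[float, ...] = (0.05, 0.1, 0.3, 0.45, 0.1)
    bl_short_probability: float = 0.0       # copy has one Butterfly/Long unit fewer
    adjacency_q: float = 0.0                # adjacent copy clones its neighbour
    structural_event_rate: float = 0.0      # per copy, planted in the coding region
    event_size_range: tuple[int, int] = (600, 8_000)
    artifact_palindrome_rate: float = 0.0   # per read
    p_unmethylated: float = 0.5
    switch_rate: float = 0.05
    cpg_density: float = 0.02
    errors: ErrorModel = field(default_factory=lambda: ErrorModel())


@dataclass
class SampleData:
    reads: list[Read]
    truths: dict[str, ReadTruth]
    methyl_calls: dict[str, list[MethylCall]]
    scenario: SampleScenario


def _draw_copy_specs(ref: SyntheticReference, n: int, sc: SampleScenario,
                     meth_states: list[str], rng: np.random.Generator
                     ) -> list[CopySpec]:
    specs: list[CopySpec] = []
    for i in range(n):
        if i > 0 and rng.random() < sc.adjacency_q:
            prev = specs[-1]
            r_count, bl_count = prev.r_count, prev.bl_count
        else:
            r_count = int(rng.choice(sc.r_count_choices, p=sc.r_count_probs))
            bl_count = ref.parts["n_bl"]
            if rng.random() < sc.bl_short_probability:
                bl_count = max(0, bl_count - 1)
        events = []
        if rng.random() < sc.structural_event_rate:
            size = int(rng.integers(sc.event_size_range[0],
                                    sc.event_size_range[1] + 1))
            etype = "deletion" if rng.random() < 0.5 else "duplication"
            pos = int(rng.integers(1_000, max(1_001, 9_000 - size)))
            events.append((etype, pos, size))
        specs.append(CopySpec(r_count, bl_count, events, meth_states[i]))
    return specs


def simulate_sample(ref: SyntheticReference, scenario: SampleScenario,
                    seed: int = 0) -> SampleData:
    """One full sample: rDNA array reads, background, decoys, methylation."""
    from .screen import locate_cut_sites

    sc = scenario
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    truths: dict[str, ReadTruth] = {}
    methyl: dict[str, list[MethylCall]] = {}

    cut_site = None
    if sc.mode == "cas9":
        sites = locate_cut_sites(ref)
        if not sites:
            raise ValueError("Cas9 mode requires guide target sites in the reference")
        cut_site = sites[0]

    L = ref.unit_length
    for i in range(sc.n_rdna_reads):
        rid = f"rdna_{i:05d}"
        n_units = int(rng.integers(sc.units_per_read[0], sc.units_per_read[1] + 1))
        states = markov_methylation_states(n_units, sc.p_unmethylated,
                                           sc.switch_rate, rng)
        specs = _draw_copy_specs(ref, n_units, sc, states, rng)
        if sc.mode == "cas9":
            # fragment cut at the guide site in the first and last copy; the
            # terminal copy contributes only its coding prefix up to the cut,
            # so the clean fragment length equals the sum of the real copies
            spec = ArraySpec(copies=specs + [CopySpec(
                ref.parts["n_r"], ref.parts["n_bl"], meth_state="M")])
            clip = sum(copy_length(ref, s) for s in specs)
            read, truth = simulate_array_read(
                ref, spec, start_phase=cut_site, n_units=n_units + 1,
                errors=sc.errors, seed=int(rng.integers(2**31)), read_id=rid,
                clip_length=clip)
        else:
            phase = int(rng.uniform(*sc.start_phase_fraction) * L)
            read, truth = simulate_array_read(
                ref, ArraySpec(copies=specs), start_phase=phase,
                n_units=n_units, errors=sc.errors,
                seed=int(rng.integers(2**31)), read_id=rid)

        if rng.random() < sc.artifact_palindrome_rate:
            read, ts_truth = simulate_template_switch(
                read, "uniform", seed=int(rng.integers(2**31)))
            truth.read_id = read.read_id
            truth.inversion_offset = ts_truth.inversion_offset
            truth.read_length = len(read)

        reads.append(read)
        truths[read.read_id] = truth
        methyl[read.read_id] = simulate_methylation_calls(
            truth, sc.cpg_density, seed=int(rng.integers(2**31)))

    for i in range(sc.n_background):
        rid = f"bg_{i:05d}"
        n = int(rng.integers(sc.background_length[0], sc.background_length[1] + 1))
        reads.append(Read(rid, _random_seq(rng, n), _quality_track(n, rng)))
        truths[rid] = ReadTruth(rid, n, is_rdna=False)

    for i in range(sc.n_decoys):
        rid = f"decoy_{i:05d}"
        span = int(rng.integers(sc.decoy_span[0], sc.decoy_span[1] + 1))
        start = int(rng.integers(0, L))
        doubled = ref.unit_sequence * (span // L + 2)
        insert = doubled[start: start + span]
        flank = _random_seq(rng, 5_000)
        seq = flank + insert + _random_seq(rng, 5_000)
        reads.append(Read(rid, seq, _quality_track(len(seq), rng)))
        truths[rid] = ReadTruth(rid, len(seq), is_rdna=False)

    return SampleData(reads, truths, methyl, sc)


def write_truth_json(truths: dict[str, ReadTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.to_json() for k, v in truths.items()}, fh, indent=1)
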