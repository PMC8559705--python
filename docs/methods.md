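# Methods

This note documents the models, parameters and numerical choices behind
`rdnarray`, and what the synthetic-data generator does and does not emulate.

## Coordinate model

All positions are 0-based, half-open, in "unit space" — coordinates on a
single repeat-unit reference.  Because a multi-unit array read is mapped
against one unit, positions wrap at the unit boundary; `circular_delta`
returns the minimal signed displacement on that circle, resolving the exact
half-circle tie to +L/2.  Every output table states this convention in its
header.  Landmarks (coding/45S interval, R-repeat interval, Butterfly/Long
interval) ship as an editable BED rather than hard-coded coordinates, so a
different species or reference accession is the same code path with a
different FASTA/BED.

## Split-and-map

Reads are cut into consecutive 300-nt sections (terminal tails ≥ 150 nt are
kept) and each section is placed independently.  The built-in aligner seeds
exact 15-mers against a circular index of the unit (k-mers spanning the
end/start junction are indexed, so sections straddling the boundary map
seamlessly) and votes on the diagonal `(reference position − section
offset) mod L`.  Diagonals are clustered within a 30-nt window to absorb
indel drift; the winning cluster's modal diagonal is the placement, ties
break to the lowest coordinate and then the forward strand, and a primary
hit requires ≥ 8 supporting k-mers (a random 300-mer against a 40-kb unit
expects ~0.01 exact 15-mer matches, so spurious placements are effectively
impossible).  Only the primary hit per section is kept — the dot-plot method
assigns one position per section.  A minimap2 subprocess backend implements
the same contract and is used as an independent cross-check; on error-free
sections the two agree exactly.

Expected spacing between consecutive mapped same-strand sections equals
their read-offset difference, signed by strand.  On the reverse strand the
coordinate tied to a section's read start is its alignment *end*, which
matters when section lengths differ (terminal tails).  `count_reference_gaps`
counts pairs deviating by strictly more than 100 nt and is the reference-
selection criterion (the best unit reference minimizes gaps);
`detect_structural_gaps` uses the same arithmetic with a strict 500-nt
threshold for noncanonical events.

## Screening

WGS mode requires (a) platform QC pass when a sequencing summary is given
(missing records pass with a logged note), (b) a continuous run of mapped
sections — tolerating up to 2 consecutive unmapped sections, i.e. isolated
mapping dropouts from sequencing error — that touches one read end and spans
≥ 40,000 nt, and (c) coding-region sections ≥ 10% of all sections.  The
length floor removes rDNA pseudogene fragments; the coding share removes
IGS-microsatellite look-alikes.  Cas9 mode extrapolates both read termini to
unit coordinates from the outermost mapped sections (strand-aware, so a
dropped terminal tail does not bias the estimate) and requires each to lie
within 50 nt of a guide cut site; cut sites default to exact matches of the
four guide target sequences in the loaded reference.

## Structure calls

Copy boundaries are placed where consecutive mapped sections cross the
reference origin in the dominant direction — the origin is an arbitrary but
canonical, reproducible per-copy boundary.  A leading/trailing segment still
counts as a complete copy when the read itself starts or ends at the origin
(tolerance 150 nt).  Segmentation requires a ≥ 0.9 dominant-strand fraction;
inverted reads go through inversion analysis instead.

Gap events: positive deviation (reference skipped) is labelled deletion,
negative (extra read sequence) duplication.  Events whose flanks both lie in
the R-repeat region, or both in the Butterfly/Long region, are suppressed as
natural variation.  A flank is assigned to a satellite region by its
reference midpoint against the interval dilated by the junction's read-space
span: when the breakpoint section itself maps to one side, the opposite
flank can sit up to roughly one junction span outside the block (e.g. loss
of the outermost — or every — satellite unit), and the dilation keeps such
junctions inside the variable region without reaching the coding region,
which is > 1 kb away from either satellite block.

Inversion triage: a read is inverted when strictly more than 10% of its
mapped sections lie on the non-dominant strand.  The inversion point is the
midpoint between the two strand runs; reads with more than one strand
transition are reported raw (`complex`) and not classified.  The
template-switch artifact model predicts a relative inversion position of
1/(1+f) ≥ 0.5 for termination fraction f, so the triage rule is: relative
position ≥ 0.5 → artifact-consistent, former half with a quality drop →
dubious, former half without → candidate real.  The ≥ 0.5 comparison is made
at the inversion point's localization resolution (one section length over
the read length): the located point is quantized to half a section, so a
fully sequenced second strand — whose true fold is exactly at 0.5 — would
otherwise be misclassified by measurement jitter.  The quality-drop detector
bins Phred scores in 200-nt bins and requires ≥ 3 consecutive bins within
2 kb after the inversion point to sit ≥ 5 Phred below the mean of the 3
preceding bins (all configurable; undetermined when the inversion is within
2 kb of the read end, treated as "no drop" for classification).  Breakpoint
recurrence across reads (single linkage within 500 nt, matching flank
orientation) is the positive evidence a genuine palindrome would leave.

## Repeat genotyping

Three 500-nt anchors from unique reference sequence flank the satellites
(human default 10,000/20,000/30,000 nt; the synthetic reference computes
them from its own layout).  Each copy segment is oriented into reference
direction and the anchors located by the same k-mer/diagonal machinery; a
duplicated anchor takes the leftmost strong hit and flags `multi_hit`.
ΔR = (anchor1→2 read distance) − (reference distance), ΔBL likewise for
anchors 2→3; ΔR/680 rounded is the derived R-copy-number change.  IGS typing
counts copies with ΔBL strictly more than 2,000 nt below reference; a sample
is "short" type when that share strictly exceeds 0.2 (a cutoff separating
the two empirically distinct groups; configurable), with ≥ 20 informative
copies required.  Homogenization: adjacent |Δ| within reads versus seeded
random distinct pairs from the whole pool, one-sided Mann–Whitney U
(adjacent stochastically smaller); all-tied input returns p = 1.

## Methylation

Input is per-read CpG posteriors (TSV: read_id, position, posterior; an
MM/ML BAM adapter produces the same records).  Both summary metrics are
computed per 200-nt bin: mean posterior ("average") and share ≥ 0.8
("threshold").  Per-copy classification uses the average metric over the
copy's coding sub-interval — strictly above 0.1 is methylated; the
unmethylated copies are the presumed active ones.  IGS methylation excludes
the Butterfly/Long span (few CpGs, variable length); sub-intervals are
derived from the copy's member sections' reference regions, so indels do not
desynchronize read and unit coordinates.  The 45S–IGS correlation is Pearson
on copies with mean 45S strictly above 0.3, pairing each copy with the IGS
*downstream* of it (the IGS inside the same origin-bounded segment); below
that stratum the 45S score carries no gradation.  The switch rate is
(different-class adjacent pairs)/(adjacent pairs), with 1/rate the implied
mean run length.  Copy number is base-weighted — total rDNA bases over total
sequenced bases, times a diploid genome size (default 6.27e9) over the unit
length — because read counts are length-confounded in WGS data.  The
constant-active-copy fit regresses proportion on 1/N through the origin
(exact least squares for p = A/N); incomplete terminal segments are excluded
from all per-copy averages.  Per-sample Spearman correlations between
R-repeat size and 45S methylation are corrected across samples with
Benjamini–Hochberg.

## Synthetic data

The generator is a pure function of (configuration, seed) throughout.

The synthetic unit places a 12-kb coding region (with the four guide targets
embedded at ~9.4–9.6 kb), an R block of 680-bp units at 13 kb, an 8-kb
spacer, a Butterfly/Long block of 4,500-bp units, and a backbone suffix;
unit length = backbone + 680·n_R + 4500·n_BL (41,040 nt with defaults
30,000/3/2).  Satellite units are internally repetitive (85-bp and 500-bp
cores) and tandem copies diverge by ~7% substitutions.  The divergence is
deliberate: real satellite arrays accumulate inter-unit variants, and exact
tandem identity would make section placement within a block formally
ambiguous (equal-score diagonals one unit apart), which no aligner can
resolve.  Anchors are computed from the layout: mid-coding, between the two
blocks, and after the Butterfly/Long block.

Array reads concatenate per-copy variants (satellite counts, optional
coding-region deletions/duplications, per-copy methylation state), drop a
start phase, and optionally clip at a Cas9 cut; the error model (defaults
3% substitution / 1% insertion / 1% deletion, a Nanopore-like ~5% total)
is applied with a coordinate map so all truth intervals are reported in
final read space.  Adjacent-copy correlation q is the probability a copy
clones its neighbour's satellite counts.  Methylation states along a read
follow a stationary two-state Markov chain parameterized by the unmethylated
fraction and a target adjacent-pair switch rate (default 1/20); posteriors
are Beta(1,20) for unmethylated and Beta(8,8) for methylated 45S copies, and
IGS CpGs draw methylated-like regardless of the 45S state.  Background reads
are uniform random sequence; pseudogene decoys are sub-40-kb rDNA fragments
in random flanks.  Genuine palindromes are an arm plus its reverse
complement read through a window covering the fold; the window placement is
drawn uniformly or on a stratified grid (the evaluation scenarios use the
grid to cover the framing range evenly).

What the generator does not emulate: homopolymer-biased and quality-
correlated Nanopore errors (errors are i.i.d. per base and qualities are a
flat track with jitter, except for the planted post-switch drop), satellite
higher-order structure beyond a single internal period, chimeric joins other
than template switching, and modified-base caller artifacts (posteriors are
drawn directly from the state's Beta).  Passing tests therefore demonstrate
correctness of the coordinate arithmetic, detection rules and statistics
under a faithful geometric model of the array, not robustness to every
platform-specific noise mode.

## Evaluation problem sizes

The evaluation scenarios (shared by the test suite and
`scripts/acceptance.py`) use: 50 error-free round-trip reads (~10,600
sections), 200 indel reads + 50 clean + 50 satellite-variation reads at 5%
error, 200 template-switch artifacts + 50 framed palindromes, 300 noisy +
50 clean genotyped copies, 200 adjacent pairs with 100 null replicates for
the homogenization test, 1,000 random bin sets / 2,000 classified copies /
2,000 switch pairs for methylation, a 128-read screening mixture for the
depth ratio, and 12 samples of 400 copies for the active-copy fit.  These
sizes put simulation noise well below each acceptance margin while keeping
the full recomputation around two minutes on one CPU.

## Known limitations

* Breakpoints are section-resolution (±~300 nt); no base-level refinement.
* Suppression of satellite-adjacent events necessarily also hides genuine
  events inside or immediately flanking the R/Butterfly-Long blocks.
* Copies are not phased to chromosomes; adjacency statistics are per read.
* The borderline between "dubious" and "candidate real" palindromes depends
  on the quality-drop heuristic, whose parameters operationalize a visual
  signature.
* The segmentation origin is the deposited unit start; biological unit
  boundaries (e.g. promoter-anchored) would shift per-copy attribution of
  IGS features by one copy for features upstream of the origin.
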