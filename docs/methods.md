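# Methods

This note documents the models and procedures `plastidtx` implements, the
defaults it chooses where the underlying conventions are ambiguous, what the
synthetic-data generator does and does not emulate, and known limitations.

## Coordinates and interval algebra

All coordinates are 1-based inclusive; feature length is `end − start + 1`.
bedGraph input (0-based half-open) is converted at the reader boundary.
Intervals never wrap the circular origin: the analyses and the simulator
place no feature across it, matching the reference tables the package ships.
The published catalog those tables transcribe reports a minimum ncRNA
length of 135 bp that is inconsistent with its own coordinates under the
inclusive convention (the shortest printed span is 136 bp, the longest
1296 bp); we keep the inclusive convention throughout and do not alter the
transcription.

Inverted-repeat duplicate gene copies are separate records sharing one
name; "unique gene" counts deduplicate by name.  One polycistron in the
printed gene table lists two tRNAs with a strand letter opposite to its
other members; since a continuous transcript is single-stranded, the loader
option `harmonize_polycistron_strands` (used by the report and acceptance
paths) reassigns labeled genes to their unit's majority strand.  This
affects exactly those two rows.

## Transcribed segments and polycistrons

Segments are maximal runs of depth ≥ `c_min`; the default `c_min = 1`
reflects the low abundance of noncoding transcripts (no coverage cutoff).
ncRNA candidacy additionally requires length ≥ `l_min = 100` bp; polycistron
evidence uses no length filter.  Same-strand segments separated by at most
`max_gap` bases are merged before unit calling; the default is 0 because
gap bridging in the reference analysis was a manual, knowledge-driven step,
and the knob exists to reproduce it deliberately rather than silently.  A
merged transcript becomes a polycistron when it overlaps ≥ 2 same-strand
genes, each over at least `member_overlap_frac = 0.5` of the gene's length —
genes in real operons are not always fully covered by reads, so exact
containment would be too strict; 0.5 is a configurable judgement call.

## ncRNA taxonomy

Segments overlapping a same-strand gene are treated as (part of) the sense
transcript and excluded, with a reason, into a side report.  Antisense
segments are classified against the opposite-strand genes they overlap,
most-specific rule first: B5 (entirely within one intron) > B4 (≥ 2 genes
overlapped; the two outermost are reported as partners) > B3B (contains a
gene's whole span) > B1/B2 (covers only the 5′ / 3′ gene boundary,
evaluated in the gene's own orientation) > B3A (strictly inside).  The
precedence resolves overlap ambiguity deterministically — an intron-
contained segment is B5 even though it is also "inside the gene".
"Partner gene" deliberately includes tRNA/rRNA/pseudogene hosts, not only
protein-coding genes, because the reference catalog lists such partners.

Intergenic segments must lie ≥ 100 bp (configurable) from the nearest
annotated transcript on both sides, looked up by boundary regardless of
strand.  A4 (bilateral) requires a mutually overlapping intergenic segment
on the opposite strand; otherwise A1/A2/A3 are assigned by flanking-gene
orientation: both flanks on the segment's strand (A1), both on the common
opposite strand (A2), discordant flanks (A3).  These semantics are
reverse-engineered from catalog exemplars rather than a written definition,
and the thresholds are exposed as configuration.

Cross-species mapping classes (1:1, 1:n, n:1, n:n) are connected components
of the bipartite query–subject graph after discarding hits with
E ≥ 10⁻⁵; classification is invariant to hit order.

## Abundance and qPCR validation

Region abundance is RPM = reads × 10⁶ / total mapped reads; a read counts
once if it overlaps the region on the matching strand, and coverage-based
input divides total base-depth by the read length.  "Arbitrary log
abundance" is log₂(RPM + ε) with ε = 1, so zero coverage scores 0; every
comparison downstream uses differences of log abundances, which are
invariant to the shared base and offset.  Report columns are rounded half
away from zero to 2 decimals.

qPCR log ratios are (40 − Ct)ₙcRNA − (40 − Ct)cRNA per technical replicate;
technical replicates are averaged within each of the three biological
replicates, and the three biological means are tested against the RNA-Seq
log ratio with a two-sided one-sample *t* test (α = 0.05).  Using
biological-replicate means rather than all nine technical values is a
documented choice; the alternative is a trivial variation.

## DNA-modification calling

Observed IPDs at a position are compared to the position's control
(unmodified-expectation) mean with a one-sided *t* test on the log scale
(modified ⇒ longer IPD), requiring coverage ≥ 10; significance is raw
p < 0.01 by default, with Benjamini–Hochberg behind a flag (raw thresholds
match the reference analysis; at genome scale expect ~1 % false positive
positions).  The reported IPD ratio is the geometric mean of the case IPDs
over the control mean: IPDs are approximately log-normal, and the geometric
ratio is exactly the location shift the test estimates, so the reported
ratio is unbiased for the underlying slowdown factor (an arithmetic-mean
ratio would be inflated by e^(σ²/2)).  The caller is a transparent
simplification of proprietary instrument pipelines; all downstream logic
consumes only (position, strand, ipd_ratio, p, coverage), so externally
produced modification tables can be substituted.

Motifs are user-supplied IUPAC strings (defaults: the two reference motifs
TATANNNATNA and WNYANTGAW); scanning reports all, including overlapping,
matches on both strands.  A motif occurrence is "modified" if at least one
significant call falls anywhere within its span on its strand (whether the
reference analysis required a specific offset is unknown; "anywhere" is the
default and a fixed-offset mode is configurable).  The modal modified
offset is reported 0-based from the motif start, strand-oriented, ties
toward the smallest; the offset from the motif end is printed alongside
because the anchoring of published "position modified" values is unstated,
and neither is asserted against them.

## Association analyses

* **asRNA vs cRNA**: Welch's two-sample *t* (unequal variances; the
  pooled-variance variant is a flag) of protein-coding gene log abundances,
  grouped by whether the gene partners any antisense catalog record;
  a secondary breakdown groups asRNA-bearing genes by partner position
  (5′ / 3′ / coding / intron).
* **Modification vs downstream expression**: motif occurrences are linked
  to same-strand transcripts whose 5′ start lies 100–500 bp downstream
  (gap measured motif-end to transcript-start; the window is a config pair —
  an abstract-level "less than 400 bp" variant exists in the source
  material and can be set).  A one-way ANOVA compares downstream ncRNA log
  abundance between modified and unmodified groups (α = 0.01); for two
  groups F equals the squared pooled *t*, asserted in tests.
* **Insertion sites**: candidate gaps are intergenic spaces ≥ 20 bp between
  adjacent genes of one polycistron; the score is the minimum of the two
  flanking genes' log abundances (conservative reading of "highly
  expressed"; a mean-score option exists).  Ranking is deterministic,
  descending score with genome-position tie-breaks.

## Synthetic-data generator

The generator lays the genome out as non-overlapping cassettes with fixed
margins, which makes placement deterministic and retry-free: operon
cassettes (3 genes, 50 bp intra-gaps), one cassette per planted ncRNA
subtype, standalone genes of which a subset carries an antisense partner,
and motif sites each followed by a same-strand downstream ncRNA at a
100–500 bp gap.  `genome_length` defaults to auto-sizing around the layout
(≈ 20–30 kb under defaults); an explicit smaller length raises a placement
error naming the constraint.

Defaults defining the study conditions:

| parameter | default | meaning |
|---|---|---|
| abundance_mean, abundance_sd | 5.0, 1.0 | per-transcript log₂ RPM law |
| asrna_effect | +2.0 log₂ | cRNA boost when an asRNA is planted |
| mod_expression_effect | +1.5 log₂ | ncRNA boost downstream of a modified motif |
| mod_ipd_ratio | 3.0 | IPD slowdown at modified positions |
| ipd_noise | 0.6 | sd of log IPD per observation |
| kinetics_coverage | 50 | observations per position |
| control_ipd_sd | 0.2 | positional control-IPD variation |
| total_mapped_reads | 10⁶ | RPM denominator (RPM = read count) |
| ct_noise | 0.25 cycles | qPCR technical noise, efficiency 1.0 |

The abundance sd of 1.0 log₂ units represents within-condition biological
spread between transcripts of a common class; the two planted effects
mirror strong, clearly visible contrasts.  Read depth is uniform over each
transcript at `count × read_length / length` with Poisson (default),
negative-binomial or exact counts, floored at depth 1 so every planted
transcript is detectable under the minimal-coverage-1 rule — this floor
slightly inflates the estimated abundance of transcripts far below the
mean.  Ct values follow `intercept − log₂RPM/log₂(1+efficiency) + noise`
with efficiency 1.0 (perfect doubling; no standard curve is modelled).
Motif instantiations are validated to contain no nested match of any
configured motif, and the background sequence is screened so that scanning
recovers exactly the planted occurrences.  The manifest (`truth.json`)
records every planted feature, abundance and modified position.

What the generator does **not** emulate: read-level sampling (no FASTQ, no
positional coverage noise within a transcript), sequencing errors, RNA
degradation gradients, overlapping same-strand transcription, features
across the circular origin, and real kinetic context effects beyond a
per-position control mean.  Passing tests therefore demonstrate correctness
of the algorithms under the stated statistical model, not robustness to
every artefact of real libraries.

A note on bilateral ncRNAs: an A4 region is by construction a pair of
overlapping transcripts, one per strand, so one planted A4 cassette
contributes two catalog records; round-trip tests compare against the
manifest, which lists both.

## Test problem sizes

Calibration and power checks in the suite use: 10 000 null positions
(caller type-I), 400 modified + 1000 null positions at coverage 50
(sensitivity/false-call rate), 67 genes (40 with asRNA) × 20 seeds for the
asRNA contrast plus 300 null seeds, and 60 motif occurrences (30 links per
modification group) × 20 seeds for the downstream-expression ANOVA.  These
sizes keep each property estimable with comfortable binomial margins while
the full suite runs in well under a minute of simulation time.

## Known limitations

* The kinetic caller is a deliberately simple location test; it does not
  model context-dependent polymerase kinetics or classify modification
  types (m6A/m4C/m5C).
* A-subtype semantics are inferred from exemplars, not a formal definition.
* Genes are assigned to polycistrons by fractional overlap with a merged
  transcript; isoform structure and spliced alignments are out of scope.
* The homology-mapping step consumes tabular hits; it does not run the
  alignment itself.
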