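# Methods

## Scope and model

The package reconstructs the post-alignment half of a transcriptome
discovery study. Its unit of evidence is the splice junction: an intron
interval `[start, end)` with a read count, taken from the aligner's
junction file. All coordinates are 0-based half-open internally; GTF I/O
converts from 1-based inclusive, genePred/BED/bedGraph are native.

**Non-redundant reference.** Two transcripts are identical iff they
agree on chromosome, strand, the full exon chain, and CDS start/stop.
The first-seen representative (in user-supplied track order) is kept, so
permuting tracks changes labels but no set cardinality. Locus footprints
are the strand-merged union of transcript spans; "intergenic" is the
strand-agnostic complement, so an exon inside another gene's intron is
*not* intergenic. Transcripts identical in exons/CDS but differing in
UTR ends are kept separate (the exon chain is part of the identity key);
this is the stricter of the two defensible readings.

**Junction partitioning.** A junction is annotated iff its intron
exactly matches a catalog intron; strand is compared only when both
sides are stranded ('.' matches either, '+' never matches '−'). No
fuzzy matching: a 1 bp offset is novel.

**Event classification.** Windows are closed intervals:

* internal exon: ordered novel-junction pair (A, B) with
  `B.start − A.end ∈ [15, 650]`; the exon is `[A.end, B.start)`. Host
  transcripts must anchor both outer junction ends inside (or on the
  boundary of) annotated exons; anchoring containment is closed so a
  junction coordinate that coincides with an exon edge anchors. Pairs
  without a common host are routed to novel-gene candidacy rather than
  discarded.
* exon skip: junction start on an exon end and junction end on a later
  exon start of the same transcript, with ≥ 1 whole exon strictly
  enclosed. One event per junction, attributed to the host with most
  skipped exons; other hosts are recorded as secondary.
* alt splice site: one end equal to an annotated intron boundary, the
  other `[15, 350]` bp from that intron's partner boundary, and not
  itself an exon boundary of the host. Side assignment is strand-aware
  (variant acceptor → alt3, variant donor → alt5; on the minus strand
  the donor is the genomic right end). Effect is `removes_sequence`
  when the novel intron is longer than the annotated one, else
  `adds_sequence`. When several annotated introns qualify, the smallest
  absolute shift wins (deterministic tie-break).
* terminal exon: a junction side with no pairing partner and no
  annotation at the landing point. The exon extent is the contiguous
  coverage run (depth ≥ 5 by default) from the junction-proximal edge,
  capped at 650 bp. Acceptance requires ≥ 50 bp of run; a candidate with
  an annotated host must not overlap the host's UTR span or any
  annotated exon; a hostless candidate must belong to a novel chain of
  ≥ 3 putative exons (internal exons in its connected component plus
  free junction ends).

Event priority is internal exon > skip > alt site: a junction consumed
by a higher class is not re-reported, which keeps per-class counts
mutually exclusive. Classification is order-independent (all outputs are
coordinate-sorted).

**Frame consequences.** The event is spliced into the host exon chain,
the mRNA rebuilt from the genome (minus-strand transcripts
reverse-complemented), and the CDS offset recomputed. Codons are read
with the standard code; a codon containing N is skipped as non-stop.
`orf_maintained` requires the net CDS length change ≡ 0 (mod 3) *and*
the first stop encountered from the annotated start to be the annotated
stop. Frameshifts and premature stops are merged into one label, as the
two are not distinguishable at the event-count level. Edits wholly
within a UTR are `utr`, subdivided: `utr_orf` iff (a) the CDS
translation is unchanged, (b) the added sequence, read on the codon grid
projected out from the annotated start (boundary-spanning codons
included), contains no stop, and (c) for 5′ UTR edits no new in-frame
upstream ATG lacking an intervening in-frame stop is created. All three
sub-criteria are recorded on the call so the policy is auditable;
removal-only UTR edits pass (b) vacuously. Multi-host events are
classified against every host and the most ORF-preserving call is
reported (configurable to most-disruptive).

**Novel genes.** Candidate exons (unanchored internal + hostless
terminal) are nodes; a novel junction joining one exon's end to
another's start is an edge. A connected component is reported iff every
exon is intergenic (one annotated-overlapping exon rejects the whole
component), it has ≥ 3 exons, and the exon-base-weighted mean depth is
strictly > 5. Isoform multiplicity is reported as the count of distinct
junction paths from the first to the last exon, not assembled
individually. Coding potential scans all six frames for ATG-initiated,
stop-terminated ORFs; strictly > 80 aa (excluding the stop) is
protein-coding. Homology search is out of scope: candidate ORFs are
written as protein FASTA for an external tool.

**Capture design.** Eligibility: feature length (exon length or |shift|)
in [15, 400] — skips carry no novel sequence and are exempt from this
rule; ≥ 50 bp of annotated flank available on each side; total captured
sequence (feature + flanks) in [300, 500] bp. Flanks grow symmetrically
from 50 bp until the 300 bp floor, capped by exon availability and the
500 bp ceiling. Baits are 120-mers tiled at step `bait_len/3` = 40 bp in
the target's composite coordinate space, last bait right-aligned, giving
~3× interior coverage (interior mean ∈ [2.5, 3.0] for targets ≥ 2 bait
lengths). A target validates in a sample iff its defining novel
junction(s) appear at exact coordinates with ≥ 1 read (threshold
configurable); novel-exon targets require both flanking junctions under
the default strict policy.

**Expression.** RPKM = reads / (length/1000) / (total/10⁶); copies per
cell span [RPKM/4, RPKM/1]. Exon detection is mean per-base depth ≥
threshold, inclusive. When per-transcript read counts are unavailable,
exonic reads are estimated as the coverage depth integral divided by the
read length (default 100 bp). Saturation curves require nested
subsamples and verify nestedness (per-base depth monotone) before
computing detection fractions. Inter-sample concordance is the fraction
of shared transcripts whose detection status (RPKM ≥ 1) agrees — a
documented stand-in for an otherwise unspecified metric.

**Report.** All derived totals (class sums, alt3+alt5, coding split,
percentages) are computed from raw counts, never re-entered, and a
consistency pass re-derives them and raises on any mismatch. Percentages
round half-up.

## The synthetic study

The generator writes a complete miniature study: random genome, designed
gene models, three partially redundant annotation tracks (track A holds
every gene; B and C resample with probability 0.6, yielding exact
duplicates for the dedup stage), junction counts, coverage, and a truth
table. It is constructive — each planted event is built so its
downstream call follows from the construction:

* Coding genes have fully-UTR first and last exons; the CDS covers the
  interior exons completely, starts with ATG, contains no internal stop
  in frame, and ends with TAA. Interior exon lengths are multiples of 3
  except two adjacent "frame-breaker" pairs (+1/+2 and +2/+1 bp), so
  codon phase is 0 at most introns and nonzero only inside the pairs.
  In-frame events (inserts with length ≡ 0 mod 3 built from stop-free
  codons; skips of whole codon-aligned exons; alt shifts ≡ 0 mod 3 at
  phase-0 introns with stop-free added segments) are guaranteed
  `orf_maintained`; frameshift events use lengths ≢ 0 mod 3 or target
  the breaker exons.
* UTR inserts designed as ORF-maintaining use a C/T-only alphabet
  ending in C: such sequence cannot form a stop codon or ATG in any
  frame, even in codons spanning the insert boundary. Disrupting
  inserts place a TAA on the codon grid projected from the annotated
  start.
* Planted novel junctions are spaced (at most one event per intron,
  with a free intron between events, minimum intron 800 bp) so that no
  unintended junction pair falls in the 15–650 bp pairing window; a
  global all-pairs post-check enforces this and fails the simulation
  rather than emit ambiguous truth.
* Junction counts: annotated counts are scaled so their aggregate is
  ~128× the novel aggregate (the magnitude observed in deep tissue
  data); 4% / 9% of classifiable novel junctions are then re-planted
  against a dedicated low-count annotated counterpart to be
  more-abundant / equally-abundant, echoing the observed
  novel:annotated abundance spectrum while keeping the aggregate ratio
  within its 2× band.
* Coverage is painted deterministically from per-gene expression levels
  (depth log-uniform over ~1–200) plus novel features at depth 8–30,
  not from simulated reads — sufficient for every consumer and fast.
  Novel genes are placed in intergenic gaps with ≥ 700 bp buffers; ~15%
  carry a planted 90-aa ORF (ATG + 89 stop-free codons + TAA) on an
  otherwise C/T background, the rest have no ATG at all.

Default conditions: 2 chromosomes × 1.6 Mb, 100 genes of 18–20 exons
(18% non-coding), 200 internal exons (18/30/52 in-frame/frameshift/UTR,
34% of UTR inserts ORF-maintaining), 50 terminal exons, 150 skips
(15/53/32, in-frame skips averaging 1.2 exons), 75+75 alt3/alt5
(23/56/21, 40% adding sequence), 20 novel genes. A run takes ~1.5 s, so
the full planted load is used directly in the test suite.

What the generator does *not* emulate: splice-site motifs (GT–AG is
never checked), sequencing noise or mismapping, fuzzy junction ends,
overlapping genes, alternative isoforms per annotated gene, biased
coverage within exons, and desk-scale totals mean RPKM magnitudes are
arbitrary units rather than realistic per-cell copy numbers. Passing
tests therefore demonstrate the correctness of the geometric and
arithmetic machinery on clean evidence, not robustness to alignment
noise — noise handling is the upstream aligner's concern in this
design.

## Numerical and degenerate-input choices

* All window bounds ([15, 650], [15, 350]) are closed; abundance-ratio
  boundaries are deterministic (fold exactly 2.0 → novel_major, exactly
  0.5 → annotated_major); detection thresholds are inclusive (≥).
* A zero-read annotated comparator gives an infinite fold
  (novel_major). Junctions with no site-sharing annotated partner are
  left unclassified and excluded from the ratio histogram denominator.
* The "corresponding annotated junction" is the maximum-read junction
  sharing a same-role splice site (start-with-start or end-with-end);
  a summing policy is available as a config switch.
* Duplicate junction rows merge by summing reads; parse errors carry
  1-based line numbers; a skip that removes the CDS start codon raises
  a classification error rather than silently dropping the event.
* Deterministic outputs everywhere: events, targets and genes are
  coordinate-sorted before id assignment (`EV######`, `NG<k>`), and the
  same seed reproduces byte-identical simulation files.

## Known limitations

* Terminal-exon extent is defined by the coverage run, so a terminal
  exon abutting another covered feature would be over-extended; the
  generator keeps planted terminals isolated, and real data would need
  the 650 bp cap plus curation.
* Exon-skip counting is per junction (hosts beyond the maximal one are
  secondary annotations), and internal-exon counting is per exon
  interval; alternative conventions would change counts on redundant
  annotation.
* Capture baits are tiled in composite (spliced-target) coordinates;
  the genomic envelope in the BED output spans any intervening introns
  rather than splitting baits across pieces.
* The UTR "ORF-maintaining" definition is a documented policy (CDS
  unchanged + projected-frame stop-free + no new uORF ATG), one of
  several defensible readings; its sub-criteria are reported per event
  so downstream users can re-slice.
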