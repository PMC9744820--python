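# Methods

## The assay model

The package models a prime-editor tag-insertion assay. A Cas9/pegRNA complex
cuts bluntly 3 bp upstream of the PAM (between protospacer positions 17/18,
standard Cas9 biochemistry); reverse transcription from the pegRNA writes a
21-nt tag into the break, anchored at the upstream end. Because reverse
transcription can stop early, insertion products are full-length or
3'-truncated. Tn5 tagmentation fragments the genome, and anchored PCR pairs
one primer inside the tag with the Tn5 adapter: forward primers read
tag → downstream genome, reverse primers tag → upstream genome. The Tn5
adapter carries a 10-nt UMI followed by a fixed 4-nt spacer at the start of
the Tn5-side read (the assay only states that UMIs are embedded in the
adapters; length and placement are configuration-driven with this default).

## Read preparation and the extension filter

Primer identification matches read 5' ends against the configured primer
panel with ≤ 1 mismatch (ties: fewest mismatches, then longest primer, then
declared order). Nested panel primers share 5' anchors, so matching is
restricted to the primers actually used in the enrichment reaction (default
pair F1 + R2); an unrestricted match can only establish read-compatibility,
not reaction identity.

The extension filter compares the `min(min_ext, boundary_offset)` bases
immediately 3' of the primer against the known tag continuation,
exact-match: the window is 2–6 bases, so tolerating a mismatch would defeat
it. Raising `min_ext` is monotonically stricter and caps at the primer's
designed boundary offset; the default (`min_ext = 8`) uses every primer's
full window. Default boundary offsets are F1/F2/F3 = 6/4/2 and R1/R2 = 2/5;
the larger offsets on the default enrichment pair keep the probability that
a random genomic continuation passes by coincidence at 4⁻⁶ (F1) and 4⁻⁵
(R2) per read.

Two consequences of tag truncation are deliberate model behavior, not filter
errors. First, a product whose retained tag is shorter than the primer's
annealing region never amplifies and is never emitted. Second, a product
that amplifies but whose truncation falls inside the extension window fails
verification — that is the assay's sensitivity cost for partial products,
and it is why the truth ledger records per read whether the extension window
in the emitted read actually matches (`ext_intact`), including the rare case
where the genomic base following a truncated tag continues it by
coincidence. Filter accuracy is therefore assessed against `ext_intact`, not
against "was a tag present at all".

## Site calling

Deduplication keys reads by (chrom, strand, 5' position, UMI, primer),
keeping the highest-mapq representative; it is idempotent, and distinct
molecules that collide in all five fields (~n²/2·4⁻¹⁰ per position) merge,
exactly as a UMI consensus would. Junction positions (aligned 5' ends, i.e.
the soft-clip boundary of the tag) cluster within 25 bp — a window inherited
from anchored-PCR practice; the assay itself states none — and the cluster
cut is the modal junction among extension-verified reads, ties toward the
smaller coordinate.

Candidate criteria:

1. **Wild-type silence** — deduplicated primer-matched WT evidence within
   the window ≤ `max_wt` (default 0). Random-priming loci are sequence-
   determined, so they recur in the WT library and this criterion removes
   them even when extension coincidentally passes. An optional relative mode
   is out of scope here; the strict zero default is the conservative
   reading.
2. **Extension evidence** — ≥ 1 extension-verified read in some direction
   and geometric mean `√(ext_fwd·ext_rev) > 0`. With the default
   `bidirectional_required = true` this demands both directions; the
   switch exposes the weaker one-direction reading because the criterion's
   two clauses are redundant under the strict one.
3. **Strandedness** — extension-verified reads present on both sides of the
   cut with the orientation the amplicon design implies (forward reads
   co-oriented with the protospacer downstream of the cut, reverse reads
   opposite and upstream). Site orientation is inferred from the majority
   forward-read strand, so minus-strand protospacers are handled
   symmetrically. Presence, not exclusivity, is required: a site receiving
   a model-(v) donor join legitimately shows extra upstream forward signal
   and must still be callable.

The PEAC score is `10⁶·ext_fwd/N_fwd + 10⁶·ext_rev/N_rev` with per-side
*deduplicated* library sizes as denominators (deduplication precedes all
counting). The exact arithmetic of the published scores is not stated; this
RPM-sum is a documented reconstruction, and only relative ranks are asserted
anywhere. PEAC-IDs are assigned in descending score order, called sites
first, rejected clusters continuing the numbering so the site table doubles
as the audit log.

Spacer matching scans both strands exhaustively for 20-mers followed by
NGG/NAG whose implied cut lies within ± 25 bp of the cluster cut, keeping
the minimal-mismatch match (≤ 7), ties broken NGG before NAG, then implied-
cut distance, then plus strand, then coordinate. PAM-N is never a mismatch;
NAG's A is reported separately (`pam_variant`) and in profile positions
22/23, since the published profiles do not state whether PAM deviations are
pooled — both are emitted.

## Translocations

Junction reads are split alignments whose 5' segment (≥ 20 bases, plus
strand) ends within 50 bp of a receiver cut. The 3' segment resolves the
joined end — plus strand ⇒ donor downstream end at its start, minus strand ⇒
inverted donor upstream end at its end — and unaligned bases between the
segments are searched for ≥ 6-base stretches of the tag in either
orientation (6 matches the simulator's truncation floor). Joins landing
within 50 bp of the receiver count as intra-site (models i/ii) and
accumulate into the normal-join count `n` together with contiguous reads;
inter-site events (iii/iv/v) are scored `t/(n + t + c)`. Geometries outside
the five models (e.g. a tagged downstream end) classify as "unassigned",
never silently dropped. Events with < 2 deduplicated reads are reported but
flagged low-confidence. The pseudocount default is 10 (the figure-legend
form of the score; the prose omits it) and is configurable. Amplicon reads
without UMIs deduplicate by position alone, as the key then degenerates
naturally.

The unexpected-upstream-signal detector flags candidate sites with ≥ 2
extension-verified forward-primer reads on the upstream/wrong-strand side of
the cut — the geometry only a reverse-oriented donor tag (model v) can
produce.

## The simulator

The generator's defaults are the study conditions used throughout the tests:
100 kb reference at GC 0.41; one on-target plus six off-targets carrying 1–6
spacer mismatches, alternating strands, ≥ 2 kb apart; 50 000 read pairs of
150 bases; edit rates 0.8 for the on-target and 0.5→0.1 tapering for
off-targets with insertion rate 0.2 everywhere; tag truncation 60 %
full-length with the remainder uniform over 6–20 retained bases; fragment
lengths truncated-normal (mean 350, sd 80, floor 80); 2 % random-priming and
5 % unenriched background pairs; 50/50 forward/reverse sub-libraries (the
molar ratio is unstated in the assay description, so equal is assumed).
Random priming initiates only at genomic loci exactly matching a primer's
3'-terminal 8 bases (either strand), mirroring the artifact the extension
filter was designed against; the emitted read is primer + genomic
continuation, since the primer is physically incorporated into the product.

Tag-free junction molecules (models ii–iv) present nothing for the
enrichment primers to anneal to, so the enrichment library realizes only
tag-carrying joins (i and v); a separate nested-PCR-style junction library
(`simulate_junction_library`, reads anchored 60 bp upstream of the receiver
cut) realizes all five, with model (ii) given 35 bp of end resection per
side — a perfect tag-free religation is sequence-identical to unedited
genome and unobservable by any read-based method. Model (i) versus (ii)
assignment (tagged versus untagged intra-site religation) is itself a
documented choice, as the published figure legend groups them without
further text.

The truth ledger records one row per emitted pair (origin, UMI, intended
alignment, retained tag length, extension-window status) and a truth SAM
carries the error-free intended alignment of every genomic segment with the
tag portion soft-clipped, so the whole pipeline runs without an external
aligner. Sequencing errors are independent substitutions at a flat rate;
base qualities are constant. Not modelled: PCR-cycle amplification bias,
realistic quality profiles, chromatin effects on editing, indels at
religation joints (beyond the model-(ii) resection), and multi-chromosome
references — passing tests therefore demonstrate pipeline correctness on
libraries with this structure, not robustness to alignment artifacts or
error modes the simulator does not emit.

## Numerical and reproducibility choices

All randomness flows through one root seed via keyed, hash-derived
sub-streams, so adding reads to one library cannot shift another; repeated
runs are byte-identical (no timestamps, sorted or insertion-ordered
iteration everywhere, plain FASTQ rather than gzip). Coordinates are 0-based
half-open internally; 1-based numbers appear only in spacer-position
columns, which follow the field's 1–20 / PAM 21–23 convention. Problem sizes
in the tests and the acceptance script (50 k pairs end-to-end, 20 k for the
filter study, 3 k for junctions, 200 spacer-oracle cases) were chosen so
each planted feature receives hundreds of covering fragments — comfortably
above the ≥ 500-fragment recoverability regime — while the full suite runs
in about two minutes.
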