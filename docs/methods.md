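# Methods

## Coordinate conventions

All genomic intervals are 0-based half-open on the forward strand, the
convention shared by PSL and BED. PSL rows for minus-strand hits store
query coordinates on the reverse-complemented read; the parser normalises
them to the forward read axis at load time so that the "reverse order
relative to the read" test for back-splice geometry is performed on a
single consistent axis. Alignment blocks are kept sorted by genomic
position; on minus-strand hits ascending genomic blocks therefore run
descending on the read.

## Read quality

Phred scores relate to per-base error probability via `err = 10^(−Q/10)`.
The mean quality of a read is the Phred value of the *mean error
probability*, not the arithmetic mean of Phred values: averaging Phred
values directly overweights high-quality bases, and the error-domain mean
is the convention of long-read QC tooling. The arithmetic-mean convention
remains available through `mean_quality(..., method="mean_phred")` and the
`quality_method` argument of `filter_reads`, since upstream filtering tools
are not explicit about which convention they use. Filtering keeps reads
with mean quality ≥ 7 and length ≥ 250 nt, both inclusive.

## BSJ calling

A BLAT-style score is computed per hit as matches − mismatches − gap
openings, counting one penalty per gap opening on either axis (the PSL
score convention; the source text says only "gap penalties"). Two hits of
one read form a BSJ candidate iff: same chromosome and strand; combined
genomic span ≤ 1 Mb (measured on the span, which *is* the putative
circRNA); genomic overlap < 50 bp; reversed order (the read-5′ hit maps to
greater genomic coordinates on `+`, smaller on `−`); and score ≥ 30 on each
side. Rejections carry the first failed criterion, checked in the order
chromosome, strand, distance, overlap, order, score.

Reads with ≥ 3 hits on one (chromosome, strand) locus within 1 Mb, all
scoring ≥ 30, and with ≥ 2 non-colinear adjacencies on the read axis (the
next segment starts genomically before the current one ends) are classified
`multi_round`: rolling reverse transcription around the circle produces
such concatemers and counting them as circRNA support would inflate
quantification, so they are reported separately and never called. Reads
none of whose hits reach score 30 are `unmapped_for_circ`; everything else
is `linear_like`. The residual-class boundary is our own choice — the
source pipeline does not define one.

## End correction

Both circRNA ends must be anchorable. Rule 1: if each end lies within 30 bp
of an annotated exon boundary on the candidate strand (exon genomic starts
for the circRNA start, exon genomic ends for the end — acceptor and donor
sides respectively in transcript orientation), each end snaps to its
nearest boundary; ties prefer the boundary giving the longer circRNA, then
the smaller coordinate, for deterministic output. Rule 2 (only if rule 1
fails): if the span's Jaccard overlap with a known-circRNA record reaches
0.95, the ends snap to the record and its ids attach. The published
criterion says "95% overlap" without naming the denominator; Jaccard was
chosen because it is symmetric and penalises both over- and under-hang, and
the threshold is exposed (`known_jaccard`). Candidates failing both rules
are excluded. Per read, the total adjustment is the sum of absolute bp
moved at the two ends; collapsed circRNAs report its min/max/mean.

## Collapsing

Candidates on mitochondrial chromosomes (chrM/MT aliases) or overlapping a
gene model flagged rRNA are removed before collapsing. rRNA exclusion keys
on an explicit flag in the gene-model table rather than name matching, to
avoid fragile regexes. One output row per (chromosome, strand, start, end);
the host gene is the model with maximal span overlap; database ids come
from end-correction rule 2 and from exact coordinate matches against the
catalogs; a circRNA with no id is novel.

## Intron retention

Per supporting read, annotation overlap (gene / exon / intron / EST layers,
each an independent merged interval set) is summed over the read's blocks
when its two hits are combined. The circRNA-level intronic fraction is the
mean intron-mapped bp divided by the mean gene-mapped bp over supporting
reads. Per intron inside the circRNA span, the spanning-read count and the
union coverage fraction are computed from raw block positions. A retained
intron requires: ≥ 20 spanning BSJ reads, coverage ≥ 0.90 of the intron
length (both inclusive), circRNA-level intronic fraction strictly above
0.03, and no novel exon detected inside the intron. The 3% gate is applied
at circRNA level and the 20-read/90% gates per intron — the most literal
reading of the published procedure, which states the fraction as a property
of the circRNA.

## Novel exons

Scanning uses *raw* (uncorrected) block coordinates: end correction would
move the very boundaries whose flanks are being tested. Within each hit,
blocks separated by ≤ 10 bp are merged (small internal deletions are
sequencing artifacts, not introns); merging never crosses the BSJ because
it is per hit. Reads whose mapping collapses to a single segment are
single-exon evidence and are skipped — a single-exon circRNA is seen as two
partial mappings of one exon whose interior break has no splice flanks. A
segment is an exon candidate iff the genome shows AG immediately 5′ and GT
immediately 3′ of it in transcript orientation (genomic AC…CT for
minus-strand loci). Exon identity for corroboration is the exact (start,
end) pair after merging; candidates with ≥ 2 supporting reads are kept.
Categories: Jaccard ≥ 0.95 against an annotated exon → known; partial
overlap → cryptic novel, with flags for which splice site (if either) is
shared; no overlap → unique novel. Partial overlap without a shared
boundary is still cryptic — the category is defined by overlap, the shared
site is recorded separately. A side effect worth knowing: a fully retained
intron read produces one merged exon–intron–exon segment that carries valid
outer flanks and therefore surfaces as a cryptic-exon candidate spanning
the intron; it does not affect the retained-intron call because the
novel-exon veto applies only to exons *inside* the intron.

Microexons are novel exons of 3–29 nt, subclassed 3–15 and 16–29.

## Reading frame

An exon is in-frame iff its length is a multiple of 3. Stop codons
(TAA/TAG/TGA) are scanned only in the single phase dictated by the nearest
annotated exon upstream in transcript orientation: if that exon is entered
at phase p and has length L, the novel exon is entered at phase
(p + L) mod 3, and codons are read starting at offset (3 − phase) mod 3,
considering only codons fully inside the exon (junction-spanning codons are
ignored). With no phased upstream exon, all three phases are scanned and
the result is flagged phase-unknown.

## Exon usage

A read spans an exon when its corrected genomic span contains the exon
interval entirely (a partial span cannot witness exclusion) and uses it
when ≥ 1 bp of its blocks falls inside. The usage level is using/spanning;
records with fewer using reads than the mode gate (10 for nick, 50 for
panel) are marked suppressed. The linear-inclusion statistic, used for
circular-vs-linear comparisons, is the fraction of linear-transcript reads
spanning both flanking exons that contain the exon.

## Conservation

20-bp anchors at both circRNA ends are lifted through a chain map. An
anchor maps only if all 20 bases lie inside a single ungapped chain block
(any base in a gap is unmappable — strict full-anchor mapping); among
covering chains the highest score wins, ties by file order, mirroring
best-chain liftover behaviour. The lifted anchors recombine into a BSJ
(strand flipped when the chain flips); a pair of circRNAs is conserved iff
the recombined BSJ exactly equals the partner's coordinates *and* the
reverse lift reproduces the original — no tolerance window, matching the
exact-match criterion. Internal splice structure is deliberately ignored.

## Simulator

The generator's default conditions: 2 chromosomes of 20 kb, 5 genes each
(3–5 exons of 100–250 nt, introns of 150–400 nt), one circRNA per gene
spanning its exons, depth 30 reads per isoform, exactly one nick per
molecule at a uniform position on the circle, no concatemers, zero error,
mean base quality 12 (per-base Phred drawn from a normal with sd 3 and
clipped to [2, 40] — clipping rather than re-sampling keeps the draw
deterministic and the distinction is immaterial at this mean), and 70% of
circRNAs entered into the known catalogs. Depth 30 and ≥ 10 loci are the
scale at which every calling gate (20-read intron gate, 2-read exon gate,
10-read usage gate) is exercised while the whole suite runs in seconds.
Introns are written with canonical splice dinucleotides so planted exons
carry correct flanks; every gene receives coding phases propagated in
transcript order from phase 0.

The feature suite plants, on seven distinct loci: a fully retained intron
(all molecules retain it), a partially retained one (half do), a 60-nt
unique novel exon, a 25-nt cryptic extension sharing the transcript-3′
splice site, microexons of 12 and 20 nt, and a 9-nt in-frame exon with a
stop codon placed in the dictated phase. Planted coordinates are recorded
for oracle tests.

PSL ground truth is emitted directly — the hits an ideal aligner would
report, one per pass over the circle — rather than running an aligner; this
keeps the pipeline logic isolated from aligner behaviour. Noise modes:
per-base mismatches (applied consistently to sequence and match counts),
and a ragged-end mode trimming up to N bp from the outer ends of each hit
to exercise the 30-bp snap. What the simulator does **not** model:
homopolymer-biased nanopore errors, basecaller artifacts, insertions and
deletions inside alignments, chimeric library artifacts, multi-nick
molecules, RNase R resistance, or expression-level variation. Passing the
oracle tests therefore demonstrates correctness of the calling logic under
clean and moderately noisy geometry, not end-to-end accuracy on real
nanopore data.

A nick falling exactly at the BSJ yields a colinear single-hit read
(classified linear-like), and a nick within 30 bp of the junction leaves
one side below the score threshold; at depth 30 over ≥ 450-nt circles every
locus retains two-hit support with overwhelming probability, which is why
zero-error recovery is exactly 100%.

## Degenerate inputs and numerical choices

Empty PSL input produces a zero summary with fractions flagged undefined
rather than NaNs. Zero filtered reads likewise. Empty intron or read lists
return empty tables. The span-Jaccard of zero-length unions is defined as
0. All thresholds sit in one `PipelineConfig` whose defaults equal the
published values; every run writes the resolved config next to its outputs
and re-running with an unchanged config hash is a no-op.

## Known limitations

- The EST annotation layer is accepted but empty by default; no EST
  download is attempted.
- Reads with more than two hits are classified (multi-round or linear)
  but never salvaged into candidate pairs; whether the original analysis
  salvaged them is unknown.
- Usage "using" is ≥ 1 bp of overlap; with exact simulated alignments this
  is unambiguous, on noisy real alignments a minimum-overlap fraction may
  be preferable (exposed as `min_use_bp`).
- Conservation requires full 20/20-base anchor mapping; orthologs whose
  ends fall in small chain gaps are missed.
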