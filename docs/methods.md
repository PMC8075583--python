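# Methods

This note documents the models, conventions and numerical choices behind
`ribopause`, in the spirit of a package's own methods appendix. It states
no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Coordinates and annotation

All coordinates are 0-based half-open everywhere in the API; the GTF's
1-based inclusive convention is converted only at the parser boundary.
CDS intervals are taken to **include the stop codon** (the simulator
writes them that way and the parser assumes it); this keeps the
stop-relative codon arithmetic (masking at P-site = stop−1, stop−2)
self-consistent without a separate stop_codon feature. Transcripts whose
CDS length is not a multiple of 3, or is shorter than 9 codons, are
flagged non-analyzable and excluded from pause/codon statistics but kept
for counting. Biotypes come from the `transcript_biotype`/`transcript_type`
attribute; values outside {protein_coding, nonsense_mediated_decay,
retained_intron} map to "other".

Each coding transcript carries a codon grid anchored on its reading
frame (`anchor = cds_start mod 3`), so UTR positions fall into in-frame
pseudo-codons. This makes 5′/3′UTR pause sites representable on the same
axis as CDS sites, at the cost of discarding reads whose A-site lands in
the ≤ 2 nt before the anchor (they are tallied, preserving count
conservation).

## Footprints, offsets, profiles

Reads of 27–34 nt (full query length, soft-clips included; primary
alignments only) are retained. P-site offsets are calibrated per read
length by maximizing, over offsets 10–18 nt, the number of reads whose
inferred P-site lands on an annotated start codon; ties break to the
smaller offset and length classes with < 100 usable reads fall back to
12 nt. This start-codon-peak calibration is this package's own
self-contained procedure for locating ribosomal sites from the offset
between footprint 5′ ends and initiation peaks. A-site = P-site + 3 nt.

The metagene profile averages per-transcript-normalized P-site density
(each transcript's in-window density sums to 1) in windows around start
and stop codons; transcripts whose UTR cannot host the window are
skipped. Because the simulator places footprint 5′ ends deterministically
relative to sampled codons (no sub-codon jitter), simulated nt-resolution
density is 3-nt periodic by construction; flatness checks in the tests
therefore bin to codon resolution.

## Pause detection

z_i = (c_i − μ)/σ per transcript per sample, with μ, σ over CDS codons;
population SD by default, with `sample_sd` and `utr_in_baseline` switches
exposed because the upstream convention is not uniquely determined. UTR
pseudo-codons are scored against the same CDS-derived baseline so UTR and
CDS pauses share a scale. σ = 0 (perfectly uniform transcript) emits no
candidates; the coverage gate (CDS mean ≥ 0.5 reads/codon) is inclusive.

A useful identity: for a single spiked codon among n CDS codons the
maximum attainable score is z = √(n−1), independent of spike height. A
z ≥ 10 pause therefore requires ≥ 102 CDS codons; the simulator's default
CDS range (150–400 codons) leaves headroom so that 30× amplification at
~2 reads/codon yields z ≈ 13–17.

Masking, collapsing and identity: a candidate's P-site codon is its
A-site codon − 1. The masked set of a gene pools, over every analyzable
isoform, the genomic first-nucleotide coordinates of start-relative
P-site codons {−3, 0, 1, 2, 3, 4} and stop-relative {−1, −2}; a candidate
is dropped when its P-site codon's genomic first-nt coordinate is in that
set. The same first-nt-in-transcript-orientation coordinate keys the
gene-level collapse, so "genomically identical" means the codon starts at
the same place in every isoform — exact here because isoforms share CDS
frames where they overlap. Per-sample locus score = arithmetic mean of z
over the transcripts reporting the pause in that sample; regions are the
union over isoforms. The replicate filter keeps a locus for a genotype
only if it is present in every replicate; classification is plain set
algebra on surviving locus keys, and a genotype-specific pause is one
that survives the filter in exactly one genotype. Unique transcript
assignment returns an isoform only when exactly one isoform's exons
contain the locus.

## Rank-sum test

Two-sided Wilcoxon rank-sum on midranks: exact when both groups have
≤ 8 observations, by dynamic programming over all C(n+m, n) rank subsets
(midranks doubled to integers, so the enumeration is exact even with
ties); otherwise the normal approximation with tie-corrected variance
and no continuity correction. The gene-set shift test and the pause-score
comparison call the same function, so they are one statistic by
construction.

## Codon occupancy

Expected reads for a codon in a transcript = total CDS reads ×
(occurrences / CDS codons). The reported ratio is plain observed/expected
(so obs = exp gives exactly 1); the test statistic is
log2((obs + ½)/exp). The half-count on the observed side only is
deliberate: beyond avoiding log 0, it is a first-order Jensen correction
for the log of Poisson-scale counts (E[log(X + ½)] ≈ log μ), and it is
what keeps the per-codon t-test calibrated under a uniform null — a
symmetric pseudocount leaves every codon ≈ −0.07 log2 biased at the
depths involved. Codons are tested across transcripts with a two-sided
one-sample t-test against 0 (constant log-ratios short-circuit to p = 1
at mean 0, p = 0 otherwise) and BH-corrected; codons seen in fewer than
3 transcripts are omitted.

## Poly(A) footprints

The terminal A-run of a read may span aligned and soft-clipped bases (N
breaks it). Templating is checked splice-aware: the run's reference
positions are reconstructed from the alignment blocks (soft-clip
extension beyond the outermost block, then aligned bases walked through
the blocks), and the run is templated only if every such base is A (T on
the reverse strand). Unmapped reads qualify on run length alone.
Qualifying reads are stripped and remapped by exact substring search
against the transcript sequences, requiring a ≥ 15 nt body — an
error-free stand-in for an aligner re-run, adequate because simulated
reads carry no mismatches. A read counts toward the poly(A) fraction only
when untemplated **and** remapped; the denominator is all retained
footprints of the sample (configurable). Genotype fractions are compared
with an equal-variance t-test (Welch available), and the maximum
protected run is reported — biologically expected to stay ≤ 15 nt, the
poly(A) span a ribosome covers up to its P-site.

## Counting, normalization, TE

Footprints are assigned to genes by the genomic position of their A-site
falling in the gene's CDS union; RNA reads by the midpoint of their
aligned interval in the exon union; reads hitting two genes' features are
discarded as ambiguous. Histone genes are removed by symbol prefix
(Hist, H1f, H2a, H2b, H3, H4; case-sensitive). Size factors are
median-of-ratios over genes nonzero in every sample, computed within each
assay separately (RPF and RNA libraries are not comparable), and rescaled
to unit geometric mean — the rescaling is what makes re-estimation on a
factor-divided matrix return exactly 1 (idempotence) while leaving
between-sample ratios untouched. log2 TE uses a pseudocount of 0.5
normalized counts on both numerator and denominator. Differential-
expression model fitting is deliberately out of scope: the Δlog2 layer
plus rank-based shift tests is the defined, testable statistic, and
externally computed significance masks can be supplied to the
opposing-regulation (buffering) analysis.

## The simulator

The generator is first-class, tested code and defines the study
conditions. Defaults: 50 genes, 1–3 isoforms (p = 0.4/0.4/0.2) sharing
CDS frames (a truncated-3′UTR isoform and an extended-5′UTR isoform
around a primary one, with an optional intron), 5′UTRs 30–90 nt, CDS
150–400 codons, 3′UTRs 60–200 nt; 2 genotypes × 3 replicates; mean depth
2 reads/codon with inter-gene abundance spread of SD 1 log2 unit and
replicate-level NB dispersion 0.05 (typical of well-behaved ribosome-
profiling replicates; gene-level spread and replicate noise are separate
on purpose, since pauses are only detectable on expressed transcripts);
footprint lengths 27–34 peaked at 28–30 with per-length P-site offsets
12–13; a 5× initiation dwell (start codon in the P-site) that powers
offset calibration; UTR sampling weight 0.05 relative to CDS. Pause
specs multiply the sampling weight of one codon (mapped across isoforms
genomically) for chosen genotypes/replicates; codon dwell multipliers act
on CDS codons; poly(A) tail reads replace a read's 3′ end with 6–15
untemplated As (cap 15, the P-site geometry constraint), 20% of them
emitted unmapped, with templated A-run decoys of 6–20 nt embedded in
3′UTRs; TE/mRNA fold changes scale the per-gene means of the footprint
and RNA draws. RNA-seq is emitted as count tables; footprints as
transcript-space and genome-space SAM (spliced CIGARs, strand-aware
soft-clipped tails). Everything is a pure function of the seed
(per-sample streams spawned from one SeedSequence), and all outputs are
byte-stable.

What the simulator does *not* model — sequencing errors, fragment-end
biases, sub-codon jitter, multimapping, UMI duplicates, partial CDS
annotations — bounds what passing tests show about real data: they
verify the statistical machinery and its logic (masking, replicate
rules, calibration, identity conventions), not robustness to alignment
artifacts.

## Verification scales

The standard designs used by the tests and the reproduction script run
at the sizes the analyses are specified at: 50 genes × 6 samples
(~180 k reads) for pause recovery, 200 single-isoform transcripts for
codon occupancy, 2000 + 100 genes × NB counts at 50 mean reads/gene × 3
replicates for the TE layer, and 300–1000 random instances per
brute-force oracle comparison. The full suite runs in well under a
minute on one CPU.

## Known limitations

- Exact remapping of stripped poly(A) bodies tolerates no mismatches;
  real data would need the aligner re-run it stands in for.
- Offset calibration assumes an initiation peak; samples treated with
  initiation-blocking drugs would need the default-offset fallback.
- The mask/collapse identity keys on codon first-nt coordinates and is
  exact only when isoforms share reading frames at the locus, as real
  same-gene isoforms nearly always do.
- GFF3 and chromosome aliases are unsupported (GTF only); genome-space
  pause profiling requires projecting alignments through the annotation.
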