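# ribopause

Ribosome-profiling analysis of translation elongation defects:
**pause-site detection**, **untemplated 3′ poly(A) footprints**, and a
**translational-efficiency (TE) / gene-set layer**, driven end-to-end by a
deterministic synthetic-footprint simulator with ground truth.

The package targets the quality-control questions raised by ribosome-rescue
mutants (no-go / non-stop decay factors such as Pelota–HBS1L): do ribosomes
stall at discrete sites genome-wide, do they run into poly(A) tails of
prematurely polyadenylated mRNAs, and how do footprint and mRNA abundance
shift relative to each other? It is a library first (import `ribopause`),
with short narrative scripts in `examples/` and a thin `ribopause` CLI for
file-based runs.

## The statistics at the core

**Pause score.** For a transcript's per-codon A-site counts
*c₁ … c_n* (reads of 27–34 nt, A-site = 5′ end + per-length P-site offset
+ 3 nt), the pause score of codon *i* is

```
z_i = (c_i − μ) / σ
```

with μ, σ the mean and population SD over the transcript's **CDS** codons in
that sample. A pause requires z ≥ 10 on a transcript with ≥ 0.5 reads/codon.
Candidates whose P-site codon falls at start-relative codons
{−3, 0, 1, 2, 3, 4} or stop-relative codons {−1, −2} *in any isoform of the
gene* are masked; survivors are collapsed across isoforms by the genomic
coordinate of the A-site codon (score = mean z over reporting transcripts),
kept only if detected in **every replicate** of a genotype, and classified
control-only / shared / mutant-only. Note the statistic's intrinsic ceiling:
a single spiked codon on an *n*-codon CDS cannot exceed z = √(n−1).

**Untemplated poly(A) footprints.** Reads ending in ≥ 6 adenosines that do
not match the reference at their aligned/soft-clipped positions (splice-aware)
are stripped of the A-run and validated by exact remapping of the body
(≥ 15 nt) against the transcriptome. The per-sample fraction of validated
reads is compared between genotypes with a Student's t-test; ribosomes
protect at most ~15 consecutive As (the poly(A) stretch up to the P-site).

**Codon occupancy.** Per transcript, observed/expected A-site reads per codon
(expected = uniform over CDS); per codon, a one-sample t-test of
log2((obs + ½)/exp) across transcripts with Benjamini–Hochberg correction.

**TE layer.** Median-of-ratios size factors per assay, then
log2 TE = log2((meanRPF + ½)/(meanRNA + ½)) per genotype and
Δlog2 TE = mutant − control; gene sets (e.g. 5′TOP reporters of mTORC1) are
tested with two-sided Wilcoxon rank-sum shift tests (exact by enumeration
when both groups ≤ 8), and cross-condition agreement with Pearson's r.

## Worked example

```bash
python examples/pause_detection.py
```

```
calibrated P-site offsets by read length: {27: 12, 28: 12, 29: 12, 30: 12, 31: 13, 32: 13, 33: 13, 34: 13}
pause candidates per sample: {'control_rep1': 5, 'control_rep2': 5, 'control_rep3': 5, 'mutant_rep1': 29, 'mutant_rep2': 29, 'mutant_rep3': 24}
candidates removed near start/stop codons: 1
final classification: {'control_only': 0, 'shared': 5, 'mutant_only': 10}
genes per class: {'control_only': 0, 'shared': 5, 'mutant_only': 10}
mutant-specific loci match truth: True
```

The simulator injected 30× pause amplification at 20 loci in a 50-gene,
3-replicate × 2-genotype design: 10 mutant-specific, 5 shared, and 5 present
in only two of three mutant replicates. The pipeline recovers exactly the 15
all-replicate loci with the correct genotype classes and rejects the five
2-of-3 loci — the all-replicates rule working as intended. The offset table
is recovered from the data by start-codon peak calibration per read length.

The other examples print the poly(A) fractions (≈ 0.002 with a 15-nt maximum
protected run and zero templated false positives), the codon-occupancy null
calibration and the 3× AGA dwell recovery, and the TE gene-set shift
(p ≈ 3 × 10⁻²⁶ for a +0.5 log2 injected shift) plus a translational-buffering
pattern (Pearson r ≈ −0.78 between mRNA and TE changes).

## Command line

```bash
ribopause simulate --config sim.yaml --outdir sim/   # GTF, FASTA, SAM, counts, truth
ribopause pause  --config run.yaml --z 10 --coverage 0.5
ribopause polya  --config run.yaml --min-tail 6
ribopause te     --config run.yaml --genesets tops.txt
ribopause all    --config run.yaml
```

`run.yaml` lists the annotation, reference and per-sample alignments with
genotype/replicate/assay labels; all outputs are TSV/BED with a config-hash
header, byte-identical on rerun.

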