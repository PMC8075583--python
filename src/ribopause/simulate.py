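"""Synthetic ribosome-profiling data with ground truth.

The simulator emits everything the analysis consumes — a multi-isoform
annotation (GTF + genome FASTA), transcript- and genome-space footprint
alignments (SAM), RNA count tables — together with a truth manifest, so
every pipeline stage can be verified without external data.

What it emulates: genes with 1-3 isoforms sharing CDS reading frames
where they overlap; 5'UTR/CDS/3'UTR structure with optional introns;
footprint lengths 27-34 nt with known per-length P-site offsets; an
initiation dwell peak; localized pause amplification at chosen codons
with genotype/replicate restrictions; codon-specific dwell multipliers;
negative-binomially dispersed gene expression over a replicates x
genotypes design; reads running into untemplated poly(A) tails (capped
at 15 nt, the span a ribosome can protect up to its P-site) plus
templated genomic A-run decoys; and gene-level mRNA / translational-
efficiency fold changes.  It does not model sequencing errors, fragment
biases or soft-clipped mismatches: reads are emitted pre-aligned.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TranscriptomeModel, TranscriptRecord
from .footprints import FootprintAlignment

_BASES = np.array(list("ACGT"))
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
_EXT5 = 40  # extra 5' genomic span, transcribed only by the long-5'UTR isoform
_UTR3_TRUNC = 40  # how much shorter the truncated-3'UTR isoform is
MAX_TAIL = 15


@dataclass(frozen=True)
class PauseSpec:
    """One injected pause: amplified sampling weight at a single codon.

    ``codon`` is the A-site codon index on the gene's primary isoform.
    ``genotypes``/``replicates`` restrict where the amplification acts
    (None = everywhere); 1-based replicate indices.
    """

    gene: str
    codon: int
    amplification: float = 30.0
    genotypes: tuple[str, ...] | None = ("mutant",)
    replicates: tuple[int, ...] | None = None


@dataclass(frozen=True)
class PolyASpec:
    rate: float = 0.002  # probability a footprint is a poly(A)-tail read
    tail_min: int = 6
    tail_max: int = MAX_TAIL
    unmapped_fraction: float = 0.2  # tail reads emitted as unmapped records
    templated_decoy_rate: float = 0.0  # decoy reads per emitted footprint

    def __post_init__(self) -> None:
        if self.tail_max > MAX_TAIL:
            raise ValueError(f"tail cap is {MAX_TAIL} nt")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 50
    isoform_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # P(1), P(2), P(3)
    utr5_range: tuple[int, int] = (30, 90)
    cds_codon_range: tuple[int, int] = (150, 400)
    utr3_range: tuple[int, int] = (60, 200)
    intron_prob: float = 0.7
    intron_range: tuple[int, int] = (60, 200)
    genotypes: tuple[str, ...] = ("control", "mutant")
    n_replicates: int = 3
    depth_per_codon: float = 2.0  # mean RPF reads per CDS codon at rel=1
    expr_log2_sd: float = 1.0  # inter-gene abundance spread
    nb_dispersion: float = 0.05  # replicate-level NB dispersion
    length_probs: tuple[tuple[int, float], ...] = (
        (27, 0.05), (28, 0.20), (29, 0.25), (30, 0.20),
        (31, 0.12), (32, 0.08), (33, 0.06), (34, 0.04),
    )
    p_offsets: tuple[tuple[int, int], ...] = (
        (27, 12), (28, 12), (29, 12), (30, 12),
        (31, 13), (32, 13), (33, 13), (34, 13),
    )
    init_amplification: float = 5.0  # dwell peak with the start codon in the P-site
    utr_weight: float = 0.05  # UTR sampling weight relative to CDS
    pauses: tuple[PauseSpec, ...] = ()
    dwell: tuple[tuple[str, float], ...] = ()  # codon -> multiplier
    polya: PolyASpec = PolyASpec(rate=0.0)
    decoy_a_runs: tuple[int, ...] = ()  # genomic A-run lengths embedded in 3'UTRs
    mrna_log2fc: tuple[tuple[str, float], ...] = ()  # gene -> mutant/control
    te_log2fc: tuple[tuple[str, float], ...] = ()
    gene_sets: tuple[tuple[str, tuple[str, ...]], ...] = ()
    rna_depth_factor: float = 1.0

    def sample_ids(self) -> list[str]:
        return [
            f"{g}_rep{r}"
            for g in self.genotypes
            for r in range(1, self.n_replicates + 1)
        ]


@dataclass
class SimRead:
    read_id: str
    transcript_id: str
    five_prime_pos: int  # transcript coordinate of the read 5' end
    length: int  # full read length including any tail
    a_codon: int  # codon index the A-site was sampled at (-1 for tail/decoy)
    tail: int = 0  # untemplated terminal As
    unmapped: bool = False
    decoy: bool = False


@dataclass
class TruthManifest:
    """Ground truth for everything the simulator emitted."""

    gene_abundance: dict[str, float] = field(default_factory=dict)
    pause_loci: list[dict] = field(default_factory=list)
    tail_reads: dict[str, list[dict]] = field(default_factory=dict)  # per sample
    decoy_reads: dict[str, list[str]] = field(default_factory=dict)
    decoy_runs: list[dict] = field(default_factory=list)
    sample_totals: dict[str, int] = field(default_factory=dict)
    mrna_log2fc: dict[str, float] = field(default_factory=dict)
    te_log2fc: dict[str, float] = field(default_factory=dict)
    gene_sets: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)


class Simulator:
    """Deterministic generator for one simulated experiment."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        n_samples = len(config.sample_ids())
        children = ss.spawn(2 + n_samples)
        self._rng_tx = np.random.default_rng(children[0])
        self._rng_rna = np.random.default_rng(children[1])
        self._sample_rngs = {
            sample: np.random.default_rng(child)
            for sample, child in zip(config.sample_ids(), children[2:])
        }
        self.manifest = TruthManifest(
            mrna_log2fc=dict(config.mrna_log2fc),
            te_log2fc=dict(config.te_log2fc),
            gene_sets={k: list(v) for k, v in config.gene_sets},
        )
        self._build_transcriptome()
        self._resolve_pauses()
        self._reads_cache: dict[str, list[SimRead]] = {}
        self._weights_cache: dict[str, tuple[int, np.ndarray]] = {}
        self._lengths = np.array([l for l, _ in config.length_probs])
        self._length_p = np.array([p for _, p in config.length_probs])
        self._length_p = self._length_p / self._length_p.sum()
        self._p_offsets = dict(config.p_offsets)

    # ------------------------------------------------------------------
    # transcriptome
    # ------------------------------------------------------------------

    def _rand_seq(self, rng, n: int) -> str:
        return "".join(_BASES[rng.integers(0, 4, n)])

    def _build_transcriptome(self) -> None:
        cfg = self.config
        rng = self._rng_tx
        genes: dict[str, list[str]] = {}
        transcripts: dict[str, TranscriptRecord] = {}
        sequences: dict[str, str] = {}
        chrom = "chr1"
        chrom_parts: list[str] = []
        cursor = 0
        decoys = list(cfg.decoy_a_runs)
        self._primary: dict[str, str] = {}
        self._iso_weights: dict[str, np.ndarray] = {}
        self._decoy_pos: dict[str, tuple[int, int]] = {}  # gene -> (tpos, len) on iso1

        for i in range(cfg.n_genes):
            gid = f"g{i + 1:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            u5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
            ncod = int(rng.integers(cfg.cds_codon_range[0], cfg.cds_codon_range[1] + 1))
            u3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
            n_iso = int(rng.choice([1, 2, 3], p=np.array(cfg.isoform_probs)))
            rel = float(2.0 ** rng.normal(0.0, cfg.expr_log2_sd))
            self.manifest.gene_abundance[gid] = rel

            ext5 = self._rand_seq(rng, _EXT5)
            u5_seq = self._rand_seq(rng, u5)
            body = rng.integers(0, len(SENSE_CODONS), ncod - 2)
            cds_seq = "ATG" + "".join(SENSE_CODONS[j] for j in body) + "TAA"
            u3_seq = self._rand_seq(rng, u3)
            if decoys and i % 2 == 0:
                run = decoys.pop(0)
                at = 10
                u3_seq = (
                    u3_seq[:at] + "C" + "A" * run + "C" + u3_seq[at + run + 2 :]
                )
                if len(u3_seq) != u3:  # 3'UTR too short to host the run
                    u3_seq = u3_seq[:u3].ljust(u3, "C")
                self._decoy_pos[gid] = (u5 + 3 * ncod + at + 1, run)
                self.manifest.decoy_runs.append({"gene": gid, "length": run})

            has_intron = rng.random() < cfg.intron_prob
            ilen = int(rng.integers(cfg.intron_range[0], cfg.intron_range[1] + 1)) if has_intron else 0
            isplit = int(rng.integers(15, 3 * ncod - 15)) if has_intron else 0
            intron_seq = self._rand_seq(rng, ilen)

            # locus axis, transcript orientation
            locus_seq = ext5 + u5_seq + cds_seq[:isplit] + intron_seq + cds_seq[isplit:] + u3_seq
            llen = len(locus_seq)
            spacer = 300 + int(rng.integers(0, 101))
            chrom_parts.append(self._rand_seq(rng, spacer))
            gstart = cursor + spacer
            chrom_parts.append(locus_seq if strand == "+" else _revcomp(locus_seq))
            cursor = gstart + llen

            def to_genomic(a: int, b: int) -> tuple[int, int]:
                if strand == "+":
                    return (gstart + a, gstart + b)
                return (gstart + llen - b, gstart + llen - a)

            tx_start = _EXT5  # locus-axis start of iso1/iso2
            tx_end_full = llen
            exon_bounds_full = (
                [(tx_start, _EXT5 + u5 + isplit), (_EXT5 + u5 + isplit + ilen, tx_end_full)]
                if has_intron
                else [(tx_start, tx_end_full)]
            )

            def make_record(tid, bounds, cds_start_t, seq):
                ex = [to_genomic(a, b) for a, b in bounds]
                return TranscriptRecord(
                    transcript_id=tid,
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    exons=ex,
                    cds_start=cds_start_t,
                    cds_end=cds_start_t + 3 * ncod,
                    biotype="protein_coding",
                    gene_name=gid,
                ), seq

            tx_seq_full = u5_seq + cds_seq + u3_seq
            iso_defs = [("t1", exon_bounds_full, u5, tx_seq_full)]
            if n_iso >= 2:
                short_bounds = [list(b) for b in exon_bounds_full]
                short_bounds[-1][1] -= _UTR3_TRUNC
                iso_defs.append(
                    ("t2", [tuple(b) for b in short_bounds], u5, tx_seq_full[:-_UTR3_TRUNC])
                )
            if n_iso >= 3:
                long_bounds = [list(b) for b in exon_bounds_full]
                long_bounds[0][0] = 0
                iso_defs.append(
                    ("t3", [tuple(b) for b in long_bounds], _EXT5 + u5, ext5 + tx_seq_full)
                )

            tids = []
            for suffix, bounds, cds_t, seq in iso_defs:
                tid = f"{gid}.{suffix}"
                rec, s = make_record(tid, bounds, cds_t, seq)
                transcripts[tid] = rec
                sequences[tid] = s
                tids.append(tid)
            genes[gid] = tids
            self._primary[gid] = tids[0]
            w = np.array([0.6, 0.25, 0.15][:n_iso])
            self._iso_weights[gid] = w / w.sum()

        self.genome = {chrom: "".join(chrom_parts)}
        self.model = TranscriptomeModel(
            genes=genes,
            transcripts=transcripts,
            sequences=sequences,
            gene_names={g: g for g in genes},
        )

    # ------------------------------------------------------------------
    # pause resolution
    # ------------------------------------------------------------------

    def _resolve_pauses(self) -> None:
        self._pause_boosts: dict[str, list[tuple[int, PauseSpec]]] = {}
        for spec in self.config.pauses:
            tid1 = self._primary[spec.gene]
            chrom, gpos, strand = self.model.genomic_codon_key(tid1, spec.codon)
            iso_codons = {}
            for tid in self.model.genes[spec.gene]:
                tr = self.model.transcripts[tid]
                try:
                    tpos = self.model.genome_to_transcript(tid, gpos)
                except IndexError:
                    continue
                if (tpos - tr.frame_anchor) % 3 == 0:
                    codon = tr.codon_index(tpos)
                    if codon is not None:
                        iso_codons[tid] = codon
                        self._pause_boosts.setdefault(tid, []).append((codon, spec))
            self.manifest.pause_loci.append(
                {
                    "gene": spec.gene,
                    "chrom": chrom,
                    "pos": gpos,
                    "strand": strand,
                    "amplification": spec.amplification,
                    "genotypes": list(spec.genotypes) if spec.genotypes else list(self.config.genotypes),
                    "replicates": list(spec.replicates)
                    if spec.replicates
                    else list(range(1, self.config.n_replicates + 1)),
                    "isoform_codons": iso_codons,
                }
            )

    # ------------------------------------------------------------------
    # footprints
    # ------------------------------------------------------------------

    def _base_weights(self, tid: str) -> tuple[int, np.ndarray]:
        """Codon sampling weights for one isoform (pause boosts excluded).

        Returns (first allowed codon index, weight vector)."""
        if tid in self._weights_cache:
            return self._weights_cache[tid]
        cfg = self.config
        tr = self.model.transcripts[tid]
        max_a_off = max(self._p_offsets.values()) + 3
        c_lo = 0
        while tr.codon_start(c_lo) < max_a_off:
            c_lo += 1
        c_hi = tr.n_codons
        while tr.codon_start(c_hi - 1) > tr.length - 21:
            c_hi -= 1
        dwell = dict(cfg.dwell)
        w = np.empty(c_hi - c_lo)
        seq = self.model.sequences[tid]
        anchor = tr.frame_anchor
        first_cds, last_cds = tr.cds_first_codon, tr.cds_last_codon
        for j, c in enumerate(range(c_lo, c_hi)):
            if first_cds <= c <= last_cds:
                w[j] = dwell.get(seq[anchor + 3 * c : anchor + 3 * c + 3], 1.0)
            else:
                w[j] = cfg.utr_weight
        init_codon = first_cds + 1  # A-site here puts the start codon in the P-site
        if c_lo <= init_codon < c_hi:
            w[init_codon - c_lo] *= cfg.init_amplification
        self._weights_cache[tid] = (c_lo, w)
        return c_lo, w

    def reads(self, sample_id: str) -> list[SimRead]:
        if sample_id not in self._reads_cache:
            self._reads_cache[sample_id] = self._generate_sample(sample_id)
        return self._reads_cache[sample_id]

    def _generate_sample(self, sample_id: str) -> list[SimRead]:
        cfg = self.config
        genotype, rep = sample_id.rsplit("_rep", 1)
        rep = int(rep)
        mutant = genotype != cfg.genotypes[0]
        rng = self._sample_rngs[sample_id]
        mrna = dict(cfg.mrna_log2fc)
        te = dict(cfg.te_log2fc)
        reads: list[SimRead] = []
        idx = 0
        for gid in sorted(self.model.genes):
            tids = self.model.genes[gid]
            ncod = (
                self.model.transcripts[self._primary[gid]].cds_end
                - self.model.transcripts[self._primary[gid]].cds_start
            ) // 3
            mean = cfg.depth_per_codon * ncod * self.manifest.gene_abundance[gid]
            if mutant:
                mean *= 2.0 ** (mrna.get(gid, 0.0) + te.get(gid, 0.0))
            n_reads = _nb_draw(rng, mean, cfg.nb_dispersion)
            split = rng.multinomial(n_reads, self._iso_weights[gid])
            for tid, n_iso_reads in zip(tids, split):
                if n_iso_reads == 0:
                    continue
                c_lo, w = self._base_weights(tid)
                for codon, spec in self._pause_boosts.get(tid, []):
                    applies = (
                        (spec.genotypes is None or genotype in spec.genotypes)
                        and (spec.replicates is None or rep in spec.replicates)
                        and c_lo <= codon < c_lo + w.size
                    )
                    if applies:
                        w = w.copy()
                        w[codon - c_lo] *= spec.amplification
                codons = rng.choice(w.size, size=n_iso_reads, p=w / w.sum()) + c_lo
                lengths = rng.choice(self._lengths, size=n_iso_reads, p=self._length_p)
                tr = self.model.transcripts[tid]
                for c, ln in zip(codons, lengths):
                    five_p = tr.codon_start(int(c)) - (self._p_offsets[int(ln)] + 3)
                    reads.append(
                        SimRead(
                            read_id=f"{sample_id}.r{idx}",
                            transcript_id=tid,
                            five_prime_pos=five_p,
                            length=int(ln),
                            a_codon=int(c),
                        )
                    )
                    idx += 1
        reads = self._convert_tails(rng, sample_id, reads)
        reads.extend(self._decoy_reads(rng, sample_id, len(reads)))
        self.manifest.sample_totals[sample_id] = len(reads)
        return reads

    def _convert_tails(
        self, rng, sample_id: str, reads: list[SimRead]
    ) -> list[SimRead]:
        spec = self.config.polya
        tail_truth: list[dict] = []
        if spec.rate > 0:
            flips = rng.random(len(reads)) < spec.rate
            for i in np.flatnonzero(flips):
                read = reads[i]
                seq = self.model.sequences[read.transcript_id]
                k_hi = min(spec.tail_max, read.length - 15)
                if k_hi < spec.tail_min:
                    continue
                k = int(rng.integers(spec.tail_min, k_hi + 1))
                body_len = read.length - k
                five_p = read.five_prime_pos
                ok = False
                for shift in range(4):  # nudge off terminal/reference A runs
                    fp = five_p - shift
                    end = fp + body_len
                    if fp < 0 or end + k > len(seq):
                        continue
                    if seq[end - 1] != "A" and set(seq[end : end + k]) != {"A"}:
                        five_p, ok = fp, True
                        break
                if not ok:
                    continue
                unmapped = bool(rng.random() < spec.unmapped_fraction)
                body = seq[five_p : five_p + body_len]
                n_hits = sum(s.count(body) for s in self.model.sequences.values())
                reads[i] = SimRead(
                    read_id=read.read_id,
                    transcript_id=read.transcript_id,
                    five_prime_pos=five_p,
                    length=read.length,
                    a_codon=-1,
                    tail=k,
                    unmapped=unmapped,
                )
                tail_truth.append(
                    {
                        "read_id": read.read_id,
                        "tail": k,
                        "unmapped": unmapped,
                        "unique_body": n_hits == 1,
                    }
                )
        self.manifest.tail_reads[sample_id] = tail_truth
        return reads

    def _decoy_reads(self, rng, sample_id: str, n_total: int) -> list[SimRead]:
        spec = self.config.polya
        out: list[SimRead] = []
        ids: list[str] = []
        if spec.templated_decoy_rate > 0 and self._decoy_pos:
            n_dec = int(rng.poisson(spec.templated_decoy_rate * n_total))
            genes = sorted(self._decoy_pos)
            for j in range(n_dec):
                gid = genes[j % len(genes)]
                tid = self._primary[gid]
                tpos, run = self._decoy_pos[gid]
                j_as = int(rng.integers(6, min(run, MAX_TAIL) + 1))
                ln = int(rng.choice(self._lengths, p=self._length_p))
                end = tpos + j_as
                five_p = end - ln
                if five_p < 0:
                    continue
                rid = f"{sample_id}.d{j}"
                out.append(
                    SimRead(
                        read_id=rid,
                        transcript_id=tid,
                        five_prime_pos=five_p,
                        length=ln,
                        a_codon=-1,
                        decoy=True,
                    )
                )
                ids.append(rid)
        self.manifest.decoy_reads[sample_id] = ids
        return out

    # ------------------------------------------------------------------
    # alignment views
    # ------------------------------------------------------------------

    def read_seq(self, read: SimRead) -> str:
        seq = self.model.sequences[read.transcript_id]
        body = seq[read.five_prime_pos : read.five_prime_pos + read.length - read.tail]
        return body + "A" * read.tail

    def footprint_alignments(self, sample_id: str) -> list[FootprintAlignment]:
        """Transcript-space view (unmapped tail reads excluded)."""
        out = []
        for read in self.reads(sample_id):
            if read.unmapped:
                continue
            out.append(
                FootprintAlignment(
                    read_id=read.read_id,
                    ref=read.transcript_id,
                    five_prime_pos=read.five_prime_pos,
                    length=read.length,
                    sample_id=sample_id,
                    strand="+",
                    ref_start=read.five_prime_pos,
                    ref_end=read.five_prime_pos + read.length - read.tail,
                    soft_clip_3p="A" * read.tail,
                    seq=self.read_seq(read),
                )
            )
        return out

    def genome_alignments(self, sample_id: str) -> list[FootprintAlignment]:
        """Genome-space view, including unmapped tail reads."""
        out = []
        for read in self.reads(sample_id):
            seq = self.read_seq(read)
            if read.unmapped:
                out.append(
                    FootprintAlignment(
                        read_id=read.read_id,
                        ref=None,
                        five_prime_pos=-1,
                        length=read.length,
                        sample_id=sample_id,
                        seq=seq,
                    )
                )
                continue
            tr = self.model.transcripts[read.transcript_id]
            blocks = self._project(
                read.transcript_id,
                read.five_prime_pos,
                read.five_prime_pos + read.length - read.tail,
            )
            gstart = min(b[0] for b in blocks)
            gend = max(b[1] for b in blocks)
            five_prime = gstart if tr.strand == "+" else gend - 1
            out.append(
                FootprintAlignment(
                    read_id=read.read_id,
                    ref=tr.chrom,
                    five_prime_pos=five_prime,
                    length=read.length,
                    sample_id=sample_id,
                    strand=tr.strand,
                    ref_start=gstart,
                    ref_end=gend,
                    soft_clip_3p="A" * read.tail,
                    seq=seq,
                    blocks=tuple(blocks),
                )
            )
        return out

    def _project(self, tid: str, start: int, end: int) -> list[tuple[int, int]]:
        """Genomic blocks (ascending) of a transcript interval."""
        tr = self.model.transcripts[tid]
        blocks = []
        off = 0
        for s, e in tr.exons:
            n = e - s
            a, b = max(start, off), min(end, off + n)
            if a < b:
                if tr.strand == "+":
                    blocks.append((s + (a - off), s + (b - off)))
                else:
                    blocks.append((e - (b - off), e - (a - off)))
            off += n
        return sorted(blocks)

    # ------------------------------------------------------------------
    # RNA
    # ------------------------------------------------------------------

    def rna_counts(self) -> pd.DataFrame:
        """Per-gene RNA-seq counts honoring the mRNA fold-change spec."""
        cfg = self.config
        rng = self._rng_rna
        mrna = dict(cfg.mrna_log2fc)
        genes = sorted(self.model.genes)
        cols = {}
        for sample in cfg.sample_ids():
            genotype = sample.rsplit("_rep", 1)[0]
            mutant = genotype != cfg.genotypes[0]
            counts = []
            for gid in genes:
                ncod = (
                    self.model.transcripts[self._primary[gid]].cds_end
                    - self.model.transcripts[self._primary[gid]].cds_start
                ) // 3
                mean = (
                    cfg.depth_per_codon
                    * cfg.rna_depth_factor
                    * ncod
                    * self.manifest.gene_abundance[gid]
                )
                if mutant:
                    mean *= 2.0 ** mrna.get(gid, 0.0)
                counts.append(_nb_draw(rng, mean, cfg.nb_dispersion))
            cols[f"{sample}_rna"] = counts
        return pd.DataFrame(cols, index=genes)

    # ------------------------------------------------------------------
    # file output
    # ------------------------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.model, outdir / "annotation.gtf")
        write_fasta(self.genome, outdir / "genome.fa")
        for sample in self.config.sample_ids():
            self.write_sam(sample, outdir / f"{sample}.transcriptome.sam", "transcript")
            self.write_sam(sample, outdir / f"{sample}.genome.sam", "genome")
        self.rna_counts().to_csv(outdir / "rna_counts.tsv", sep="\t")
        (outdir / "truth.json").write_text(self.manifest.to_json())

    def write_sam(self, sample_id: str, path: str | Path, space: str) -> None:
        lines = ["@HD\tVN:1.6\tSO:unknown"]
        if space == "transcript":
            for tid in sorted(self.model.transcripts):
                lines.append(f"@SQ\tSN:{tid}\tLN:{self.model.transcripts[tid].length}")
        else:
            for chrom in sorted(self.genome):
                lines.append(f"@SQ\tSN:{chrom}\tLN:{len(self.genome[chrom])}")
        for read in self.reads(sample_id):
            seq = self.read_seq(read)
            if space == "transcript":
                if read.unmapped:
                    continue
                aligned = read.length - read.tail
                cigar = f"{aligned}M" + (f"{read.tail}S" if read.tail else "")
                lines.append(
                    f"{read.read_id}\t0\t{read.transcript_id}\t{read.five_prime_pos + 1}"
                    f"\t255\t{cigar}\t*\t0\t0\t{seq}\t*"
                )
                continue
            if read.unmapped:
                lines.append(f"{read.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*")
                continue
            tr = self.model.transcripts[read.transcript_id]
            blocks = self._project(
                read.transcript_id,
                read.five_prime_pos,
                read.five_prime_pos + read.length - read.tail,
            )
            parts = []
            for (s1, e1), (s2, _) in zip(blocks, blocks[1:]):
                parts.append((e1 - s1, s2 - e1))
            cigar_core = ""
            for (m, gap) in parts:
                cigar_core += f"{m}M{gap}N"
            cigar_core += f"{blocks[-1][1] - blocks[-1][0]}M"
            if tr.strand == "+":
                flag = 0
                out_seq = seq
                cigar = cigar_core + (f"{read.tail}S" if read.tail else "")
            else:
                flag = 16
                out_seq = _revcomp(seq)
                cigar = (f"{read.tail}S" if read.tail else "") + cigar_core
            lines.append(
                f"{read.read_id}\t{flag}\t{tr.chrom}\t{blocks[0][0] + 1}"
                f"\t255\t{cigar}\t*\t0\t0\t{out_seq}\t*"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def _nb_draw(rng, mean: float, dispersion: float) -> int:
    """One negative-binomial count with Var = mean + dispersion * mean^2."""
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    shape = 1.0 / dispersion
    return int(rng.negative_binomial(shape, shape / (shape + mean)))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def write_gtf(model: TranscriptomeModel, path: str | Path) -> None:
    """Write the model as a Gencode-dialect GTF (CDS includes the stop
    codon; 1-based inclusive coordinates)."""
    from .annotation import cds_genomic_intervals

    lines = []
    for gid in sorted(model.genes):
        for tid in model.genes[gid]:
            tr = model.transcripts[tid]
            attrs = (
                f'gene_id "{gid}"; transcript_id "{tid}"; '
                f'gene_name "{tr.gene_name or gid}"; transcript_type "{tr.biotype}";'
            )
            for s, e in sorted(tr.exons):
                lines.append(
                    f"{tr.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{tr.strand}\t.\t{attrs}"
                )
            if tr.is_coding:
                for s, e in cds_genomic_intervals(model, tid):
                    lines.append(
                        f"{tr.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{tr.strand}\t.\t{attrs}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    lines = []
    for name in sorted(sequences):
        lines.append(f">{name}")
        seq = sequences[name]
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_te_experiment(
    seed: int,
    n_background: int = 2000,
    set_size: int = 100,
    delta_log2_te: float = 0.5,
    mean_reads: float = 50.0,
    dispersion: float = 0.05,
    expr_log2_sd: float = 0.5,
    n_replicates: int = 3,
    mrna_log2fc: dict[str, float] | None = None,
    te_log2fc: dict[str, float] | None = None,
):
    """Gene-level count simulation for the TE / gene-set layer.

    With the default arguments a ``delta_log2_te`` shift is injected into
    the first ``set_size`` genes ("te_set"); explicit per-gene
    ``mrna_log2fc``/``te_log2fc`` dicts override that and allow buffering
    designs.  Returns ``(CountMatrix, truth)`` where truth carries the
    per-gene true changes and the set membership.
    """
    from .translatome import CountMatrix

    rng = np.random.default_rng(seed)
    n_genes = n_background + set_size
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    if te_log2fc is None:
        te_log2fc = {g: delta_log2_te for g in genes[:set_size]}
    if mrna_log2fc is None:
        mrna_log2fc = {}
    rel = 2.0 ** rng.normal(0.0, expr_log2_sd, n_genes)
    te = np.array([te_log2fc.get(g, 0.0) for g in genes])
    mrna = np.array([mrna_log2fc.get(g, 0.0) for g in genes])

    cols, meta = {}, []
    for genotype, is_mut in (("control", False), ("mutant", True)):
        for r in range(1, n_replicates + 1):
            rpf_mean = mean_reads * rel * (2.0 ** (mrna + te) if is_mut else 1.0)
            rna_mean = mean_reads * rel * (2.0 ** mrna if is_mut else 1.0)
            rpf_id, rna_id = f"{genotype}_rep{r}", f"{genotype}_rep{r}_rna"
            cols[rpf_id] = [_nb_draw(rng, m, dispersion) for m in rpf_mean]
            cols[rna_id] = [_nb_draw(rng, m, dispersion) for m in rna_mean]
            meta.append((rpf_id, "RPF", genotype, r))
            meta.append((rna_id, "RNA", genotype, r))
    counts = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(
        meta, columns=["sample_id", "assay", "genotype", "replicate"]
    ).set_index("sample_id")
    matrix = CountMatrix(counts=counts[list(samples.index)], samples=samples)
    truth = {
        "te_log2fc": dict(zip(genes, (float(x) for x in te))),
        "mrna_log2fc": dict(zip(genes, (float(x) for x in mrna))),
        "te_set": [g for g in genes if te_log2fc.get(g, 0.0) != 0.0],
        "genes": genes,
    }
    return matrix, truth
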