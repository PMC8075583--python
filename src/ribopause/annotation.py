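"""Transcript annotation: loading, validation and coordinate arithmetic.

Everything downstream (A-site profiles, pause collapsing, poly(A)
templating checks, feature counting) asks this module where things are.
All coordinates are 0-based half-open in every API; the GTF's 1-based
inclusive convention is converted at the parser boundary and nowhere else.

A transcript's codon grid is anchored on its CDS reading frame: codon *i*
spans transcript nucleotides ``[anchor + 3i, anchor + 3i + 3)`` where
``anchor = cds_start % 3``.  UTR positions therefore fall into in-frame
"pseudo-codons", which keeps 5'/3'UTR pause sites representable on the
same axis as coding ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from Bio import SeqIO
from Bio.Seq import Seq


class AnnotationError(ValueError):
    """Malformed GTF or inconsistent annotation/sequence inputs."""


class UnsupportedTranscriptError(ValueError):
    """Operation requested on a transcript that cannot support it."""


class Region(str, Enum):
    FIVE_PRIME_UTR = "five_prime_utr"
    CDS = "cds"
    THREE_PRIME_UTR = "three_prime_utr"


_KNOWN_BIOTYPES = {"protein_coding", "nonsense_mediated_decay", "retained_intron"}

# codons to analyze; anything shorter has no room for whole-codon statistics
MIN_CDS_CODONS = 9


@dataclass
class TranscriptRecord:
    """One isoform: exon structure, CDS bounds and biotype.

    ``exons`` are genomic ``(start, end)`` intervals ordered 5'->3' in
    transcript orientation (descending genomic coordinates on the minus
    strand).  ``cds_start``/``cds_end`` are *transcript* coordinates and
    include the stop codon; both are ``None`` for non-coding isoforms.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: str = "other"
    gene_name: str = ""
    analyzable: bool = True
    flag_reason: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: strand must be + or -")
        for (s, e) in self.exons:
            if e <= s:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{s},{e})")
        genomic = sorted(self.exons)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise AnnotationError(
                f"{self.transcript_id}: exons not ordered 5'->3' in transcript orientation"
            )
        self._flag_cds()

    def _flag_cds(self) -> None:
        if self.cds_start is None:
            return
        cds_len = self.cds_end - self.cds_start
        if cds_len <= 0:
            raise AnnotationError(f"{self.transcript_id}: empty CDS")
        if cds_len % 3 != 0:
            self.analyzable = False
            self.flag_reason = f"CDS length {cds_len} not a multiple of 3"
        elif cds_len < 3 * MIN_CDS_CODONS:
            self.analyzable = False
            self.flag_reason = f"CDS shorter than {MIN_CDS_CODONS} codons"

    # -- basic geometry ---------------------------------------------------

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    # -- codon grid -------------------------------------------------------

    @property
    def frame_anchor(self) -> int:
        """First transcript position on the CDS-aligned codon grid."""
        if not self.is_coding:
            raise UnsupportedTranscriptError(f"{self.transcript_id} is non-coding")
        return self.cds_start % 3

    @property
    def n_codons(self) -> int:
        return (self.length - self.frame_anchor) // 3

    def codon_start(self, codon: int) -> int:
        if not 0 <= codon < self.n_codons:
            raise IndexError(f"codon {codon} out of range for {self.transcript_id}")
        return self.frame_anchor + 3 * codon

    def codon_index(self, pos: int) -> int | None:
        """Codon containing transcript position ``pos``; None if off-grid."""
        if pos < self.frame_anchor:
            return None
        codon = (pos - self.frame_anchor) // 3
        return codon if codon < self.n_codons else None

    @property
    def cds_first_codon(self) -> int:
        return (self.cds_start - self.frame_anchor) // 3

    @property
    def cds_last_codon(self) -> int:
        """Index of the stop codon (CDS here includes the stop codon)."""
        return self.cds_first_codon + (self.cds_end - self.cds_start) // 3 - 1


@dataclass
class TranscriptomeModel:
    """Genes, isoforms and spliced sequences; the coordinate authority."""

    genes: dict[str, list[str]]
    transcripts: dict[str, TranscriptRecord]
    sequences: dict[str, str]
    gene_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for gid, tids in self.genes.items():
            for tid in tids:
                if tid in owner:
                    raise AnnotationError(f"{tid} assigned to {owner[tid]} and {gid}")
                owner[tid] = gid
        bad = [
            tid
            for tid, tr in self.transcripts.items()
            if tid in self.sequences and len(self.sequences[tid]) != tr.length
        ]
        if bad:
            raise AnnotationError(
                "sequence/annotation length mismatch for: " + ", ".join(sorted(bad))
            )
        missing = sorted(set(self.transcripts) - set(self.sequences))
        if missing:
            raise AnnotationError("transcripts missing sequence: " + ", ".join(missing))

    # -- coordinate mapping ----------------------------------------------

    def transcript_to_genome(self, transcript_id: str, pos: int) -> tuple[str, int, str]:
        tr = self.transcripts[transcript_id]
        if not 0 <= pos < tr.length:
            raise IndexError(f"position {pos} outside {transcript_id} [0,{tr.length})")
        off = pos
        for s, e in tr.exons:
            n = e - s
            if off < n:
                g = s + off if tr.strand == "+" else e - 1 - off
                return tr.chrom, g, tr.strand
            off -= n
        raise AssertionError("unreachable")

    def genome_to_transcript(self, transcript_id: str, gpos: int) -> int:
        tr = self.transcripts[transcript_id]
        off = 0
        for s, e in tr.exons:
            if s <= gpos < e:
                return off + (gpos - s if tr.strand == "+" else e - 1 - gpos)
            off += e - s
        raise IndexError(f"genomic position {gpos} not exonic in {transcript_id}")

    def genomic_codon_key(self, transcript_id: str, codon: int) -> tuple[str, int, str]:
        """Genomic identity of a codon: coordinate of its first (5') nt."""
        tr = self.transcripts[transcript_id]
        return self.transcript_to_genome(transcript_id, tr.codon_start(codon))

    # -- region classification -------------------------------------------

    def classify_region(self, transcript_id: str, pos: int) -> Region:
        tr = self.transcripts[transcript_id]
        if not tr.is_coding:
            raise UnsupportedTranscriptError(f"{transcript_id} is non-coding")
        if not 0 <= pos < tr.length:
            raise IndexError(f"position {pos} outside {transcript_id}")
        if pos < tr.cds_start:
            return Region.FIVE_PRIME_UTR
        if pos < tr.cds_end:
            return Region.CDS
        return Region.THREE_PRIME_UTR

    def codon_seq(self, transcript_id: str, codon: int) -> str:
        tr = self.transcripts[transcript_id]
        start = tr.codon_start(codon)
        return self.sequences[transcript_id][start : start + 3]

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id


def cds_genomic_intervals(model: TranscriptomeModel, transcript_id: str) -> list[tuple[int, int]]:
    """Genomic intervals (sorted, 0-based half-open) covered by the CDS
    of one transcript, split at exon boundaries."""
    tr = model.transcripts[transcript_id]
    if not tr.is_coding:
        raise UnsupportedTranscriptError(f"{transcript_id} is non-coding")
    out = []
    t = tr.cds_start
    while t < tr.cds_end:
        chrom, g, _ = model.transcript_to_genome(transcript_id, t)
        off = t
        run = 1
        for s, e in tr.exons:
            n = e - s
            if off < n:
                run = min(n - off, tr.cds_end - t)
                break
            off -= n
        if tr.strand == "+":
            out.append((g, g + run))
        else:
            out.append((g - run + 1, g + 1))
        t += run
    return sorted(out)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attrs(attr_field: str, lineno: int, required: tuple[str, ...]) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    for key in required:
        if key not in attrs:
            raise AnnotationError(f"GTF line {lineno}: missing attribute {key!r}")
    return attrs


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def load_annotation(gtf_path: str, fasta_path: str) -> TranscriptomeModel:
    """Load a Gencode-dialect GTF plus a genome or transcript FASTA.

    If the FASTA record ids cover the GTF's chromosome names, spliced
    transcript sequences are derived internally (reverse-complemented on
    the minus strand); otherwise the FASTA is taken to hold one record per
    transcript id.  CDS intervals are expected to include the stop codon.
    """
    chrom_of: dict[str, str] = {}
    strand_of: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    name_of_gene: dict[str, str] = {}
    biotype_of: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds_parts: dict[str, list[tuple[int, int]]] = {}

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"GTF line {lineno}: expected 9 columns")
            chrom, _, feature, start, end, _, strand, _, attr_field = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_attrs(attr_field, lineno, ("gene_id", "transcript_id"))
            tid = attrs["transcript_id"]
            gid = attrs["gene_id"]
            gene_of.setdefault(tid, gid)
            chrom_of.setdefault(tid, chrom)
            strand_of.setdefault(tid, strand)
            if "gene_name" in attrs:
                name_of_gene.setdefault(gid, attrs["gene_name"])
            bt = attrs.get("transcript_biotype", attrs.get("transcript_type"))
            if bt is not None:
                biotype_of.setdefault(tid, bt if bt in _KNOWN_BIOTYPES else "other")
            iv = (int(start) - 1, int(end))  # GTF is 1-based inclusive
            (exons if feature == "exon" else cds_parts).setdefault(tid, []).append(iv)

    genes: dict[str, list[str]] = {}
    transcripts: dict[str, TranscriptRecord] = {}
    for tid in exons:
        ex = sorted(exons[tid])
        strand = strand_of[tid]
        ordered = ex if strand == "+" else ex[::-1]
        rec = TranscriptRecord(
            transcript_id=tid,
            gene_id=gene_of[tid],
            chrom=chrom_of[tid],
            strand=strand,
            exons=ordered,
            biotype=biotype_of.get(tid, "other"),
            gene_name=name_of_gene.get(gene_of[tid], ""),
        )
        if tid in cds_parts:
            pieces = sorted(cds_parts[tid])
            cds_len = sum(e - s for s, e in pieces)
            five_most = pieces[0][0] if strand == "+" else pieces[-1][1] - 1
            # map the CDS 5' base through the (already validated) exon walk
            tmp_model = TranscriptomeModel(
                genes={rec.gene_id: [tid]},
                transcripts={tid: rec},
                sequences={tid: "N" * rec.length},
            )
            cds_start = tmp_model.genome_to_transcript(tid, five_most)
            rec = TranscriptRecord(
                transcript_id=tid,
                gene_id=rec.gene_id,
                chrom=rec.chrom,
                strand=strand,
                exons=ordered,
                cds_start=cds_start,
                cds_end=cds_start + cds_len,
                biotype=rec.biotype,
                gene_name=rec.gene_name,
            )
        transcripts[tid] = rec
        genes.setdefault(rec.gene_id, []).append(tid)

    fasta = {r.id: str(r.seq).upper() for r in SeqIO.parse(fasta_path, "fasta")}
    chroms = {t.chrom for t in transcripts.values()}
    if chroms <= set(fasta):
        sequences = {}
        for tid, tr in transcripts.items():
            parts = []
            for s, e in tr.exons:
                piece = fasta[tr.chrom][s:e]
                parts.append(piece if tr.strand == "+" else _revcomp(piece))
            sequences[tid] = "".join(parts)
    else:
        missing = sorted(set(transcripts) - set(fasta))
        if missing:
            raise AnnotationError(
                "transcripts absent from FASTA: " + ", ".join(missing)
            )
        sequences = {tid: fasta[tid] for tid in transcripts}

    return TranscriptomeModel(
        genes=genes,
        transcripts=transcripts,
        sequences=sequences,
        gene_names=name_of_gene,
    )
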