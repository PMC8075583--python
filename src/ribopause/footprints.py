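"""Footprint alignment ingestion, offset calibration and A-site profiles.

Ribosome-protected fragments of 27-34 nt are read from SAM/BAM (primary
alignments only), P-site offsets are calibrated per read length by
start-codon peak maximization, and per-transcript A-site count profiles
are built on the CDS-anchored codon grid of :mod:`ribopause.annotation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam

from .annotation import Region, TranscriptomeModel, UnsupportedTranscriptError

log = logging.getLogger(__name__)

MIN_FOOTPRINT_LEN = 27
MAX_FOOTPRINT_LEN = 34
OFFSET_SEARCH = range(10, 19)  # candidate P-site offsets, 5' rule
DEFAULT_P_OFFSET = 12
ASITE_SHIFT = 3  # A-site sits one codon 3' of the P-site


@dataclass
class FootprintAlignment:
    """One primary alignment, reduced to what the analysis needs.

    ``five_prime_pos`` is the position of the read's biological 5' end on
    the reference (transcript coordinate, or genomic coordinate for
    genome-space alignments).  ``seq`` is the read in its original
    (sequencing) orientation; ``soft_clip_3p`` is the unaligned 3' suffix.
    For unmapped reads ``ref`` is None and positions are -1.
    """

    read_id: str
    ref: str | None
    five_prime_pos: int
    length: int
    sample_id: str
    strand: str = "+"
    ref_start: int = -1
    ref_end: int = -1
    soft_clip_3p: str = ""
    soft_clip_5p: int = 0
    seq: str = ""
    blocks: tuple[tuple[int, int], ...] | None = None  # spliced aligned blocks

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("read length must be positive")
        if set(self.soft_clip_3p) - set("ACGTN"):
            raise ValueError("soft-clip suffix must be ACGTN")

    @property
    def aligned_blocks(self) -> tuple[tuple[int, int], ...]:
        if self.blocks is not None:
            return self.blocks
        return ((self.ref_start, self.ref_end),)


def ingest_alignments(
    path: str,
    sample_id: str,
    min_len: int = MIN_FOOTPRINT_LEN,
    max_len: int = MAX_FOOTPRINT_LEN,
    keep_unmapped: bool = False,
) -> list[FootprintAlignment]:
    """Read primary alignments with read length in ``[min_len, max_len]``.

    Secondary and supplementary records are dropped.  Read length is the
    full query length including soft-clipped bases.  With
    ``keep_unmapped`` unmapped records (``ref is None``) are retained for
    the poly(A) pathway.
    """
    out: list[FootprintAlignment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.get_forward_sequence() or ""
            if not min_len <= len(seq) <= max_len:
                continue
            if rec.is_unmapped:
                if keep_unmapped:
                    out.append(
                        FootprintAlignment(
                            read_id=rec.query_name,
                            ref=None,
                            five_prime_pos=-1,
                            length=len(seq),
                            sample_id=sample_id,
                            seq=seq,
                        )
                    )
                continue
            cigar = rec.cigartuples or []
            clip_left = cigar[0][1] if cigar and cigar[0][0] == 4 else 0
            clip_right = cigar[-1][1] if cigar and cigar[-1][0] == 4 else 0
            if rec.is_reverse:
                clip_5p, clip_3p_len = clip_right, clip_left
                five_prime = rec.reference_end - 1
                strand = "-"
            else:
                clip_5p, clip_3p_len = clip_left, clip_right
                five_prime = rec.reference_start
                strand = "+"
            out.append(
                FootprintAlignment(
                    read_id=rec.query_name,
                    ref=rec.reference_name,
                    five_prime_pos=five_prime,
                    length=len(seq),
                    sample_id=sample_id,
                    strand=strand,
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_end,
                    soft_clip_3p=seq[len(seq) - clip_3p_len :] if clip_3p_len else "",
                    soft_clip_5p=clip_5p,
                    seq=seq,
                    blocks=tuple(rec.get_blocks()),
                )
            )
    if not any(a.ref is not None for a in out):
        log.warning("%s: no retained footprints in %s", sample_id, path)
    return out


@dataclass
class OffsetTable:
    """Per-read-length P-site offsets (nt from the 5' end)."""

    p_offsets: dict[int, int]

    def __post_init__(self) -> None:
        for length, off in self.p_offsets.items():
            if not OFFSET_SEARCH.start <= off < OFFSET_SEARCH.stop:
                raise ValueError(f"offset {off} for length {length} outside [10,18]")

    def p_offset(self, length: int) -> int:
        return self.p_offsets[length]

    def a_offset(self, length: int) -> int:
        return self.p_offsets[length] + ASITE_SHIFT


def calibrate_offsets(
    alignments: list[FootprintAlignment],
    model: TranscriptomeModel,
    min_reads: int = 100,
    min_len: int = MIN_FOOTPRINT_LEN,
    max_len: int = MAX_FOOTPRINT_LEN,
) -> OffsetTable:
    """Choose, per read length, the offset that puts the most P-sites on
    annotated start codons; ties break to the smaller offset, and length
    classes with fewer than ``min_reads`` usable reads fall back to the
    default offset of 12 nt.

    Expects transcript-space alignments.
    """
    hits: dict[int, np.ndarray] = {
        ln: np.zeros(len(OFFSET_SEARCH), dtype=np.int64) for ln in range(min_len, max_len + 1)
    }
    usable = dict.fromkeys(hits, 0)
    for aln in alignments:
        if aln.ref is None or aln.ref not in model.transcripts:
            continue
        tr = model.transcripts[aln.ref]
        if not tr.is_coding or aln.length not in hits:
            continue
        usable[aln.length] += 1
        for i, off in enumerate(OFFSET_SEARCH):
            if aln.five_prime_pos + off == tr.cds_start:
                hits[aln.length][i] += 1
    table: dict[int, int] = {}
    for length in range(min_len, max_len + 1):
        if usable[length] < min_reads:
            log.warning(
                "length %d: %d usable reads (<%d); falling back to offset %d",
                length, usable[length], min_reads, DEFAULT_P_OFFSET,
            )
            table[length] = DEFAULT_P_OFFSET
        else:
            table[length] = int(OFFSET_SEARCH[int(np.argmax(hits[length]))])
    return OffsetTable(table)


@dataclass
class AsiteProfile:
    """Per-codon A-site counts for one transcript in one sample.

    The vector spans the whole transcript on the CDS-anchored codon grid
    (UTR pseudo-codons included); ``cds_codon_range`` is the inclusive
    (first, last) index pair of coding codons.
    """

    transcript_id: str
    sample_id: str
    counts: np.ndarray
    cds_codon_range: tuple[int, int]
    n_discarded: int = 0

    @property
    def cds_counts(self) -> np.ndarray:
        first, last = self.cds_codon_range
        return self.counts[first : last + 1]


def build_asite_profile(
    alignments: list[FootprintAlignment],
    offsets: OffsetTable,
    model: TranscriptomeModel,
    transcript_id: str,
    sample_id: str,
) -> AsiteProfile:
    """Assign each read's A-site to a codon; off-grid A-sites are tallied
    as discards so that counts remain conserved."""
    tr = model.transcripts[transcript_id]
    if not (tr.is_coding and tr.analyzable):
        raise UnsupportedTranscriptError(
            f"{transcript_id} not analyzable: {tr.flag_reason or 'non-coding'}"
        )
    counts = np.zeros(tr.n_codons, dtype=np.int64)
    discarded = 0
    anchor = tr.frame_anchor
    for aln in alignments:
        if aln.ref != transcript_id or aln.sample_id != sample_id:
            continue
        a_pos = aln.five_prime_pos + offsets.a_offset(aln.length)
        codon = (a_pos - anchor) // 3 if a_pos >= anchor else -1
        if 0 <= codon < tr.n_codons:
            counts[codon] += 1
        else:
            discarded += 1
    return AsiteProfile(
        transcript_id=transcript_id,
        sample_id=sample_id,
        counts=counts,
        cds_codon_range=(tr.cds_first_codon, tr.cds_last_codon),
        n_discarded=discarded,
    )


def build_profiles(
    alignments: list[FootprintAlignment],
    offsets: OffsetTable,
    model: TranscriptomeModel,
    sample_id: str,
) -> dict[str, AsiteProfile]:
    """Profiles for every analyzable transcript with at least one read."""
    by_ref: dict[str, list[FootprintAlignment]] = {}
    for aln in alignments:
        if aln.ref is not None and aln.sample_id == sample_id:
            by_ref.setdefault(aln.ref, []).append(aln)
    profiles = {}
    for tid, alns in sorted(by_ref.items()):
        tr = model.transcripts.get(tid)
        if tr is None or not (tr.is_coding and tr.analyzable):
            continue
        profiles[tid] = build_asite_profile(alns, offsets, model, tid, sample_id)
    return profiles


@dataclass
class MetageneProfile:
    """Mean normalized P-site density around start and stop codons."""

    sample_id: str
    offsets_start: np.ndarray  # nt offsets relative to the start codon
    density_start: np.ndarray
    offsets_stop: np.ndarray  # nt offsets relative to the stop codon
    density_stop: np.ndarray
    n_transcripts_start: int = 0
    n_transcripts_stop: int = 0


def metagene(
    alignments: list[FootprintAlignment],
    offsets: OffsetTable,
    model: TranscriptomeModel,
    sample_id: str,
    window: tuple[int, int] = (24, 90),
) -> MetageneProfile:
    """Average per-transcript-normalized P-site density in windows of
    ``window = (upstream, downstream)`` nt around start and stop codons.

    Each transcript's in-window density is normalized to sum to 1 before
    averaging; transcripts whose UTR cannot host the upstream (start) or
    downstream (stop) extent are skipped.
    """
    up, down = window
    span = up + down + 1
    psite_by_tid: dict[str, list[int]] = {}
    for aln in alignments:
        if aln.ref is None or aln.sample_id != sample_id:
            continue
        if aln.ref in model.transcripts:
            psite_by_tid.setdefault(aln.ref, []).append(
                aln.five_prime_pos + offsets.p_offset(aln.length)
            )
    acc_start = np.zeros(span)
    acc_stop = np.zeros(span)
    n_start = n_stop = 0
    for tid in sorted(psite_by_tid):
        tr = model.transcripts[tid]
        if not tr.is_coding:
            continue
        psites = np.array(psite_by_tid[tid])
        if tr.cds_start >= up:
            rel = psites - tr.cds_start
            vec = np.bincount(rel[(rel >= -up) & (rel <= down)] + up, minlength=span)
            if vec.sum() > 0:
                acc_start += vec / vec.sum()
                n_start += 1
        else:
            log.debug("%s: 5'UTR shorter than start window, skipped", tid)
        stop_first_nt = tr.cds_end - 3
        if tr.length - stop_first_nt - 1 >= down:
            rel = psites - stop_first_nt
            vec = np.bincount(rel[(rel >= -up) & (rel <= down)] + up, minlength=span)
            if vec.sum() > 0:
                acc_stop += vec / vec.sum()
                n_stop += 1
        else:
            log.debug("%s: 3'UTR shorter than stop window, skipped", tid)
    return MetageneProfile(
        sample_id=sample_id,
        offsets_start=np.arange(-up, down + 1),
        density_start=acc_start / n_start if n_start else acc_start,
        offsets_stop=np.arange(-up, down + 1),
        density_stop=acc_stop / n_stop if n_stop else acc_stop,
        n_transcripts_start=n_start,
        n_transcripts_stop=n_stop,
    )


def _terminal_a_run(seq: str) -> int:
    """Length of the maximal terminal run of A at the 3' end; N breaks it."""
    k = 0
    for base in reversed(seq):
        if base == "A":
            k += 1
        else:
            break
    return k


def polyA_suffix_scan(
    alignment: FootprintAlignment, reference: str
) -> tuple[int, bool]:
    """Measure the read's terminal 3' A-run and decide whether it is
    templated by the reference at the corresponding positions.

    The run may span aligned and soft-clipped bases.  ``reference`` is the
    sequence of the alignment's reference (chromosome or transcript).  A
    run is templated only when every corresponding reference base is A
    (T on the reverse strand); positions beyond the reference are
    untemplated by definition.  Spliced alignments are handled through
    the alignment blocks, so a run crossing an exon junction is checked
    against the exonic bases it actually aligned to.
    """
    k = _terminal_a_run(alignment.seq)
    if k == 0:
        return 0, False
    s3 = len(alignment.soft_clip_3p)
    blocks = alignment.aligned_blocks
    positions: list[int] = []  # reference positions of the terminal k bases
    if alignment.strand == "+":
        clip_hi = blocks[-1][1] + s3  # one past the soft-clipped 3' extension
        n_clip = min(k, s3)
        positions.extend(range(clip_hi - n_clip, clip_hi))
        need = k - n_clip
        for bs, be in reversed(blocks):  # walk aligned bases 3' -> 5'
            take = min(need, be - bs)
            positions.extend(range(be - take, be))
            need -= take
            if need == 0:
                break
        want = "A"
    else:
        clip_lo = blocks[0][0] - s3
        n_clip = min(k, s3)
        positions.extend(range(clip_lo, clip_lo + n_clip))
        need = k - n_clip
        for bs, be in blocks:  # genomic-left blocks hold the read 3' end
            take = min(need, be - bs)
            positions.extend(range(bs, bs + take))
            need -= take
            if need == 0:
                break
        want = "T"
    templated = all(0 <= p < len(reference) and reference[p] == want for p in positions)
    return k, not templated
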