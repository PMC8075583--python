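"""Untemplated 3' poly(A) footprint detection.

Footprints ending in six or more adenosines that are absent from the
reference are candidate reads from ribosomes that ran into the poly(A)
tail of a prematurely polyadenylated mRNA.  Candidates are validated by
stripping the terminal A-run and exact-matching the remaining body
against the transcriptome; only untemplated, successfully remapped reads
enter the per-sample fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotation import TranscriptomeModel
from .footprints import FootprintAlignment, _terminal_a_run, polyA_suffix_scan
from .stats import two_sample_t

log = logging.getLogger(__name__)

MIN_TAIL = 6
MIN_REMAP_BODY = 15  # nt of stripped read required for an exact-match remap


@dataclass
class PolyAReadRecord:
    read_id: str
    sample_id: str
    tail_length: int
    untemplated: bool
    remapped: bool
    remap_transcript_id: str | None = None

    @property
    def qualifies(self) -> bool:
        """Counted in the poly(A) fraction: untemplated AND remapped."""
        return self.untemplated and self.remapped


def _exact_remap(
    body: str, transcript_seqs: dict[str, str]
) -> tuple[bool, str | None]:
    for tid in sorted(transcript_seqs):
        if body in transcript_seqs[tid]:
            return True, tid
    return False, None


def detect_polyA_reads(
    alignments: list[FootprintAlignment],
    model: TranscriptomeModel,
    genome: dict[str, str] | None = None,
    min_tail: int = MIN_TAIL,
    min_body: int = MIN_REMAP_BODY,
) -> list[PolyAReadRecord]:
    """Scan genome-space alignments (and unmapped reads) for candidate
    poly(A) footprints.

    Mapped reads qualify when their terminal A-run is >= ``min_tail`` and
    untemplated against the reference; unmapped reads qualify on run
    length alone.  Qualifying reads are stripped of the run and remapped
    by exact substring match against the transcript sequences.

    ``genome`` maps chromosome -> sequence for the templating check; when
    omitted, mapped reads whose reference is missing are skipped with a
    warning.
    """
    genome = genome or {}
    records = []
    for aln in alignments:
        if aln.ref is None:
            tail = _terminal_a_run(aln.seq)
            untemplated = True
        else:
            ref_seq = genome.get(aln.ref)
            if ref_seq is None and aln.ref in model.sequences:
                ref_seq = model.sequences[aln.ref]
            if ref_seq is None:
                log.warning("no reference sequence for %s; read %s skipped",
                            aln.ref, aln.read_id)
                continue
            tail, untemplated = polyA_suffix_scan(aln, ref_seq)
        if tail < min_tail or not untemplated:
            continue
        body = aln.seq[: len(aln.seq) - tail]
        remapped, remap_tid = (
            _exact_remap(body, model.sequences) if len(body) >= min_body else (False, None)
        )
        records.append(
            PolyAReadRecord(
                read_id=aln.read_id,
                sample_id=aln.sample_id,
                tail_length=tail,
                untemplated=untemplated,
                remapped=remapped,
                remap_transcript_id=remap_tid,
            )
        )
    return records


@dataclass
class PolyAFraction:
    sample_id: str
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError(f"{self.sample_id}: zero denominator")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(f"{self.sample_id}: numerator outside [0, denominator]")


def polyA_fraction(
    records: list[PolyAReadRecord], sample_totals: dict[str, int]
) -> dict[str, PolyAFraction]:
    """Per-sample fraction of qualifying poly(A) reads among all retained
    footprints (``sample_totals``)."""
    qualifying: dict[str, int] = dict.fromkeys(sample_totals, 0)
    for rec in records:
        if rec.qualifies and rec.sample_id in qualifying:
            qualifying[rec.sample_id] += 1
    return {
        sample: PolyAFraction(sample, qualifying[sample], total)
        for sample, total in sample_totals.items()
    }


def compare_fractions(
    fractions_a: list[float], fractions_b: list[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test of per-sample fractions between
    genotypes (equal-variance by default, Welch via ``equal_var=False``)."""
    return two_sample_t(fractions_a, fractions_b, equal_var=equal_var)


def max_protected_A_run(records: list[PolyAReadRecord]) -> int:
    """Longest untemplated A-run among qualifying reads (0 when none);
    the biological expectation is a ceiling of ~15 nt, the poly(A) length
    a ribosome can cover up to its P-site."""
    tails = [r.tail_length for r in records if r.qualifies]
    return max(tails) if tails else 0
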