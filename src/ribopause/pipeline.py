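"""Composable workflows: pause detection, poly(A) scanning and the TE
layer, each a thin orchestration over the analysis modules, plus TSV/BED
writers used by the command-line interface.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import TranscriptomeModel
from .footprints import (
    FootprintAlignment,
    OffsetTable,
    calibrate_offsets,
    build_profiles,
)
from .pausing import (
    GenePause,
    PauseClassification,
    classify_pauses,
    collapse_to_gene,
    compare_pause_scores,
    mask_start_stop,
    pause_scores,
    replicate_filter,
)
from .polya import (
    PolyAFraction,
    PolyAReadRecord,
    compare_fractions,
    detect_polyA_reads,
    max_protected_A_run,
    polyA_fraction,
)
from .translatome import (
    CountMatrix,
    OpposingRegulationResult,
    ShiftTestResult,
    attach_size_factors,
    compute_te,
    drop_histones,
    geneset_shift_test,
    opposing_regulation,
)

log = logging.getLogger(__name__)


def validate_design(design: dict[str, list[str]], min_replicates: int = 2) -> None:
    if len(design) < 2:
        raise ValueError("need at least two genotypes")
    for genotype, samples in design.items():
        if len(samples) < min_replicates:
            raise ValueError(
                f"genotype {genotype!r} has {len(samples)} replicate(s); "
                f"need >= {min_replicates}"
            )


@dataclass
class PauseWorkflowResult:
    offsets: OffsetTable
    design: dict[str, list[str]]
    n_candidates: dict[str, int]
    n_masked: int
    gene_pauses: list[GenePause]
    genotype_sets: dict[str, list[GenePause]]
    classification: PauseClassification
    score_comparison: tuple[float, float] | None = None

    def pause_table(self) -> pd.DataFrame:
        samples = [s for ss in self.design.values() for s in ss]
        rows = []
        for p in sorted(self.gene_pauses, key=lambda p: p.key):
            row = {
                "gene_id": p.gene_id,
                "chrom": p.chrom,
                "pos": p.pos,
                "strand": p.strand,
                "regions": ",".join(sorted(r.value for r in p.regions)),
                "classification": p.classification or "unfiltered",
            }
            for s in samples:
                row[f"score_{s}"] = round(p.scores.get(s, float("nan")), 6)
            for genotype in self.design:
                bits = p.replicate_presence.get(genotype, ())
                row[f"presence_{genotype}"] = "".join("1" if b else "0" for b in bits)
            rows.append(row)
        return pd.DataFrame(rows)

    def bed6(self) -> pd.DataFrame:
        rows = []
        for p in sorted(self.gene_pauses, key=lambda p: p.key):
            if p.classification is None:
                continue
            start = p.pos if p.strand == "+" else p.pos - 2
            score = min(1000.0, float(np.mean(list(p.scores.values()))))
            rows.append(
                (p.chrom, start, start + 3, p.gene_id, round(score, 3), p.strand)
            )
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )


def run_pause_workflow(
    model: TranscriptomeModel,
    alignments_by_sample: dict[str, list[FootprintAlignment]],
    design: dict[str, list[str]],
    z_threshold: float = 10.0,
    coverage_threshold: float = 0.5,
    offsets: OffsetTable | None = None,
) -> PauseWorkflowResult:
    """Candidates -> start/stop mask -> genomic collapse -> all-replicate
    filter -> genotype classification, for a two-genotype design (the
    first design key is the control)."""
    validate_design(design)
    if offsets is None:
        pooled = [a for alns in alignments_by_sample.values() for a in alns]
        offsets = calibrate_offsets(pooled, model)
    candidates = []
    n_candidates = {}
    for sample in [s for ss in design.values() for s in ss]:
        alns = alignments_by_sample[sample]
        sample_cands = []
        for profile in build_profiles(alns, offsets, model, sample).values():
            sample_cands.extend(
                pause_scores(
                    profile,
                    model,
                    z_threshold=z_threshold,
                    coverage_threshold=coverage_threshold,
                )
            )
        n_candidates[sample] = len(sample_cands)
        candidates.extend(sample_cands)
    masked = mask_start_stop(candidates, model)
    log.info("masked %d of %d candidates near start/stop codons",
             len(candidates) - len(masked), len(candidates))
    gene_pauses = collapse_to_gene(masked, model)
    genotype_sets = replicate_filter(gene_pauses, design)
    genotypes = list(design)
    classification = classify_pauses(
        genotype_sets[genotypes[0]], genotype_sets[genotypes[1]]
    )
    comparison = None
    mutant_samples = design[genotypes[1]]
    m_scores = [
        float(np.mean([p.scores[s] for s in mutant_samples]))
        for p in genotype_sets[genotypes[1]]
        if p.key in classification.mutant_only
    ]
    s_scores = [
        float(np.mean([p.scores[s] for s in mutant_samples]))
        for p in genotype_sets[genotypes[1]]
        if p.key in classification.shared
    ]
    if m_scores and s_scores:
        comparison = compare_pause_scores(m_scores, s_scores)
    return PauseWorkflowResult(
        offsets=offsets,
        design=design,
        n_candidates=n_candidates,
        n_masked=len(candidates) - len(masked),
        gene_pauses=gene_pauses,
        genotype_sets=genotype_sets,
        classification=classification,
        score_comparison=comparison,
    )


@dataclass
class PolyAWorkflowResult:
    records: list[PolyAReadRecord]
    fractions: dict[str, PolyAFraction]
    comparison: tuple[float, float] | None
    max_a_run: int

    def fraction_table(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": f.sample_id,
                "qualifying": f.numerator,
                "total": f.denominator,
                "fraction": f.fraction,
            }
            for f in sorted(self.fractions.values(), key=lambda f: f.sample_id)
        ]
        return pd.DataFrame(rows)

    def record_table(self) -> pd.DataFrame:
        rows = [
            {
                "read_id": r.read_id,
                "sample_id": r.sample_id,
                "tail_length": r.tail_length,
                "untemplated": r.untemplated,
                "remapped": r.remapped,
                "remap_transcript_id": r.remap_transcript_id or ".",
            }
            for r in sorted(self.records, key=lambda r: (r.sample_id, r.read_id))
        ]
        return pd.DataFrame(rows)


def run_polya_workflow(
    model: TranscriptomeModel,
    genome_alignments_by_sample: dict[str, list[FootprintAlignment]],
    sample_totals: dict[str, int],
    design: dict[str, list[str]],
    genome: dict[str, str] | None = None,
    min_tail: int = 6,
) -> PolyAWorkflowResult:
    """Detect untemplated poly(A) footprints per sample and compare the
    per-sample fractions between the two genotypes (Student's t-test);
    the comparison is skipped with a note when no qualifying read exists."""
    records = []
    for sample in sorted(genome_alignments_by_sample):
        records.extend(
            detect_polyA_reads(
                genome_alignments_by_sample[sample],
                model,
                genome=genome,
                min_tail=min_tail,
            )
        )
    fractions = polyA_fraction(records, sample_totals)
    genotypes = list(design)
    group_a = [fractions[s].fraction for s in design[genotypes[0]]]
    group_b = [fractions[s].fraction for s in design[genotypes[1]]]
    if any(group_a) or any(group_b):
        comparison = compare_fractions(group_b, group_a)
    else:
        log.info("no qualifying poly(A) reads in any sample; comparison skipped")
        comparison = None
    return PolyAWorkflowResult(
        records=records,
        fractions=fractions,
        comparison=comparison,
        max_a_run=max_protected_A_run(records),
    )


@dataclass
class TEWorkflowResult:
    te: pd.DataFrame
    mrna_change: pd.Series
    shift_tests: dict[str, ShiftTestResult]
    opposing: OpposingRegulationResult | None

    def shift_table(self) -> pd.DataFrame:
        rows = [
            {
                "set": r.name,
                "n_set": r.n_set,
                "n_background": r.n_background,
                "statistic": r.statistic,
                "p": r.p,
                "direction": r.direction,
            }
            for r in self.shift_tests.values()
        ]
        return pd.DataFrame(rows)


def run_te_workflow(
    matrix: CountMatrix,
    control: str,
    mutant: str,
    gene_sets: dict[str, list[str]] | None = None,
    gene_symbols: dict[str, str] | None = None,
    mrna_sig: pd.Series | None = None,
    te_sig: pd.Series | None = None,
    pseudocount: float = 0.5,
    test_opposing: bool = True,
) -> TEWorkflowResult:
    """Histone removal -> per-assay median-of-ratios normalization ->
    per-gene TE and changes -> gene-set shift tests and the opposing
    mRNA/TE (buffering) analysis."""
    matrix = drop_histones(matrix, gene_symbols)
    matrix = attach_size_factors(matrix)
    te = compute_te(matrix, control, mutant, pseudocount=pseudocount)
    mrna_change = np.log2(
        (te["mean_rna_mutant"] + pseudocount) / (te["mean_rna_control"] + pseudocount)
    )
    mrna_change.name = "mrna_log2fc"
    shift_tests = {}
    for name, members in (gene_sets or {}).items():
        try:
            shift_tests[name] = geneset_shift_test(
                te["delta_log2_te"], members, name=name
            )
        except ValueError as exc:
            log.warning("gene set %s skipped: %s", name, exc)
    opposing = None
    if test_opposing:
        opposing = opposing_regulation(
            mrna_change, te["delta_log2_te"], mrna_sig=mrna_sig, te_sig=te_sig
        )
    return TEWorkflowResult(
        te=te, mrna_change=mrna_change, shift_tests=shift_tests, opposing=opposing
    )


# ----------------------------------------------------------------------
# output writing
# ----------------------------------------------------------------------


def _header(config_repr: str) -> str:
    digest = hashlib.sha256(config_repr.encode()).hexdigest()[:12]
    return f"# ribopause v{__version__} config_sha={digest}\n"


def write_table(df: pd.DataFrame, path: str | Path, config_repr: str = "") -> None:
    """TSV with a provenance header line; stable byte-for-byte under a
    fixed config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config_repr))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
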