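"""Gene-level counting, normalization, translational efficiency and the
gene-set shift / correlation layer.

TE (translational efficiency) is footprint abundance normalized to mRNA
abundance:  log2 TE_g = log2((mean normalized RPF + pc) / (mean
normalized RNA + pc)) per genotype, and the reported effect is the
mutant - control difference.  Gene-set analyses (5'TOP-style sets,
opposing mRNA/TE regulation, pause classes vs translation) are two-sided
Wilcoxon rank-sum shift tests of members against the remaining genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import TranscriptomeModel, cds_genomic_intervals
from .footprints import FootprintAlignment, OffsetTable
from .stats import pearson_r, rank_sum_test

log = logging.getLogger(__name__)

HISTONE_PREFIXES = ("Hist", "H1f", "H2a", "H2b", "H3", "H4")
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Gene x sample counts plus per-sample metadata.

    ``samples`` is indexed by sample id with columns ``assay`` (RPF|RNA),
    ``genotype`` and ``replicate``; ``size_factors`` divide counts when
    normalizing.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample table disagree")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not computed")
        return self.counts / self.size_factors

    def subset_assay(self, assay: str) -> "CountMatrix":
        keep = self.samples.index[self.samples["assay"] == assay]
        return CountMatrix(
            counts=self.counts[list(keep)],
            samples=self.samples.loc[keep],
            size_factors=None
            if self.size_factors is None
            else self.size_factors[list(keep)],
        )


def _gene_feature_index(
    model: TranscriptomeModel, feature: str
) -> dict[str, list[tuple[int, int, str]]]:
    """Per chromosome, the (start, end, gene) union intervals of the
    requested feature across all isoforms of each gene."""
    per_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gene, tids in sorted(model.genes.items()):
        spans: dict[str, list[tuple[int, int]]] = {}
        for tid in tids:
            tr = model.transcripts[tid]
            if feature == "exon":
                ivs = tr.exons
            else:
                if not tr.is_coding:
                    continue
                ivs = cds_genomic_intervals(model, tid)
            spans.setdefault(tr.chrom, []).extend((s, e) for s, e in ivs)
        for chrom, ivs in spans.items():
            for s, e in _merge(ivs):
                per_chrom.setdefault(chrom, []).append((s, e, gene))
    return per_chrom


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def count_features(
    alignments_by_sample: dict[str, list[FootprintAlignment]],
    model: TranscriptomeModel,
    samples: pd.DataFrame,
    offsets: OffsetTable | None = None,
    feature: str = "cds",
) -> CountMatrix:
    """Count reads per gene from transcript-space alignments.

    Footprints (``feature='cds'``) are assigned by the genomic position
    of their A-site; RNA reads (``feature='exon'``) by the midpoint of
    their aligned interval.  A read overlapping the feature union of more
    than one gene is discarded as ambiguous.
    """
    if feature not in ("cds", "exon"):
        raise ValueError("feature must be 'cds' or 'exon'")
    if feature == "cds" and offsets is None:
        raise ValueError("A-site counting requires an offset table")
    index = _gene_feature_index(model, feature)
    genes = sorted(model.genes)
    counts = pd.DataFrame(0, index=genes, columns=list(samples.index), dtype=np.int64)
    for sample_id, alns in alignments_by_sample.items():
        ambiguous = 0
        for aln in alns:
            if aln.ref is None or aln.ref not in model.transcripts:
                continue
            tr = model.transcripts[aln.ref]
            if feature == "cds":
                tpos = aln.five_prime_pos + offsets.a_offset(aln.length)
            else:
                aligned = aln.length - len(aln.soft_clip_3p) - aln.soft_clip_5p
                tpos = aln.five_prime_pos + aligned // 2
            if not 0 <= tpos < tr.length:
                continue
            chrom, gpos, _ = model.transcript_to_genome(aln.ref, tpos)
            hits = {
                gene
                for s, e, gene in index.get(chrom, [])
                if s <= gpos < e
            }
            if len(hits) == 1:
                counts.loc[next(iter(hits)), sample_id] += 1
            elif len(hits) > 1:
                ambiguous += 1
        if ambiguous:
            log.info("%s: %d ambiguous reads discarded", sample_id, ambiguous)
    return CountMatrix(counts=counts, samples=samples)


def drop_histones(
    matrix: CountMatrix, gene_symbols: dict[str, str] | None = None
) -> CountMatrix:
    """Remove histone genes by symbol prefix (Hist, H1f, H2a, H2b, H3,
    H4; case-sensitive).  ``gene_symbols`` maps row id -> symbol; rows
    are taken as symbols themselves when it is omitted."""
    def symbol(gene: str) -> str:
        return gene_symbols.get(gene, gene) if gene_symbols else gene

    keep = [g for g in matrix.counts.index if not symbol(g).startswith(HISTONE_PREFIXES)]
    return CountMatrix(
        counts=matrix.counts.loc[keep],
        samples=matrix.samples,
        size_factors=matrix.size_factors,
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to unit geometric mean.

    Using genes with nonzero counts in every sample, each sample's factor
    is the median of count / geometric-mean-across-samples; the final
    rescaling makes re-estimation on a factor-divided matrix return
    exactly 1 for every sample (idempotence).
    """
    arr = counts.to_numpy(dtype=float)
    everywhere = (arr > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = arr[everywhere]
    geomean = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def attach_size_factors(matrix: CountMatrix) -> CountMatrix:
    """Compute size factors within each assay separately (RPF and RNA
    libraries are not comparable) and attach them."""
    factors = pd.Series(1.0, index=matrix.samples.index)
    for assay in sorted(matrix.samples["assay"].unique()):
        cols = list(matrix.samples.index[matrix.samples["assay"] == assay])
        factors[cols] = size_factors(matrix.counts[cols])
    return CountMatrix(matrix.counts, matrix.samples, size_factors=factors)


def compute_te(
    matrix: CountMatrix,
    control: str,
    mutant: str,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene translational efficiency and its mutant-control change.

    Requires a normalized matrix with >= 1 RPF and >= 1 RNA sample per
    genotype.  Returns a DataFrame indexed by gene with mean normalized
    abundances, per-genotype log2 TE and ``delta_log2_te``.
    """
    if matrix.size_factors is None:
        matrix = attach_size_factors(matrix)
    norm = matrix.normalized()
    means = {}
    for genotype in (control, mutant):
        for assay in ("RPF", "RNA"):
            cols = list(
                matrix.samples.index[
                    (matrix.samples["genotype"] == genotype)
                    & (matrix.samples["assay"] == assay)
                ]
            )
            if not cols:
                raise ValueError(f"no {assay} samples for genotype {genotype!r}")
            means[(genotype, assay)] = norm[cols].mean(axis=1)
    out = pd.DataFrame(index=matrix.counts.index)
    for genotype, label in ((control, "control"), (mutant, "mutant")):
        rpf = means[(genotype, "RPF")]
        rna = means[(genotype, "RNA")]
        out[f"mean_rpf_{label}"] = rpf
        out[f"mean_rna_{label}"] = rna
        out[f"log2_te_{label}"] = np.log2((rpf + pseudocount) / (rna + pseudocount))
    out["delta_log2_te"] = out["log2_te_mutant"] - out["log2_te_control"]
    return out


@dataclass
class ShiftTestResult:
    name: str
    n_set: int
    n_background: int
    statistic: float
    p: float
    direction: int  # sign of median(member) - median(background)


def geneset_shift_test(
    values: pd.Series, members, name: str = "set", min_members: int = 5
) -> ShiftTestResult:
    """Two-sided rank-sum shift test of a gene set against the remaining
    genes of the supplied universe."""
    members = [g for g in members if g in values.index]
    dropped = len(set(members)) - len(members)
    if dropped:
        log.warning("%s: %d members absent from universe, dropped", name, dropped)
    if len(members) < min_members:
        raise ValueError(f"{name}: fewer than {min_members} members present")
    member_vals = values.loc[members]
    background = values.drop(index=members)
    if background.empty:
        raise ValueError(f"{name}: background is empty")
    stat, p = rank_sum_test(member_vals.to_numpy(), background.to_numpy())
    direction = int(np.sign(member_vals.median() - background.median()))
    return ShiftTestResult(
        name=name,
        n_set=len(members),
        n_background=background.size,
        statistic=stat,
        p=p,
        direction=direction,
    )


@dataclass
class OpposingRegulationResult:
    up_mrna_test: ShiftTestResult | None
    down_mrna_test: ShiftTestResult | None
    up_mrna_down_te: list[str]
    down_mrna_up_te: list[str]


def opposing_regulation(
    mrna_change: pd.Series,
    te_change: pd.Series,
    mrna_sig: pd.Series | None = None,
    te_sig: pd.Series | None = None,
    min_members: int = 5,
) -> OpposingRegulationResult:
    """Test whether TE buffers transcription: partition genes by
    significant mRNA direction and shift-test their TE changes against
    the remaining genes; list genes whose TE moves opposite to mRNA."""
    if not mrna_change.index.equals(te_change.index):
        raise ValueError("mRNA and TE vectors must share one gene universe")
    if mrna_sig is None:
        mrna_sig = pd.Series(True, index=mrna_change.index)
    if te_sig is None:
        te_sig = pd.Series(True, index=te_change.index)
    up = mrna_change.index[(mrna_change > 0) & mrna_sig]
    down = mrna_change.index[(mrna_change < 0) & mrna_sig]

    def _test(genes, name):
        try:
            return geneset_shift_test(te_change, genes, name=name, min_members=min_members)
        except ValueError:
            log.warning("%s: too few genes for a shift test", name)
            return None

    up_test = _test(up, "mrna_up")
    down_test = _test(down, "mrna_down")
    return OpposingRegulationResult(
        up_mrna_test=up_test,
        down_mrna_test=down_test,
        up_mrna_down_te=sorted(set(up) & set(te_change.index[(te_change < 0) & te_sig])),
        down_mrna_up_te=sorted(set(down) & set(te_change.index[(te_change > 0) & te_sig])),
    )


def condition_correlation(changes_a: pd.Series, changes_b: pd.Series) -> float:
    """Pearson r of per-gene changes over the shared gene universe."""
    shared = changes_a.index.intersection(changes_b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes")
    return pearson_r(changes_a.loc[shared].to_numpy(), changes_b.loc[shared].to_numpy())


def pausing_vs_expression(
    pause_classes: dict[str, set[str]],
    changes: pd.Series,
    min_members: int = 5,
) -> dict[str, ShiftTestResult]:
    """Shift tests of expression/TE changes for each pause class's genes
    against the remaining translated genes; undersized classes are
    skipped with a warning."""
    out = {}
    for cls, genes in sorted(pause_classes.items()):
        try:
            out[cls] = geneset_shift_test(
                changes, sorted(genes), name=cls, min_members=min_members
            )
        except ValueError:
            log.warning("pause class %s skipped (fewer than %d genes)", cls, min_members)
    return out
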