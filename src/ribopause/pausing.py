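"""Ribosome pause-site detection, masking, gene-level collapsing,
replicate logic, genotype classification and codon occupancy statistics.

A pause is a codon whose A-site count is an outlier relative to its own
transcript: z = (c_i - mu) / sigma with mu and sigma taken over the CDS
codons of that transcript in that sample (population SD by default).
Candidates require z >= 10 and a transcript mean of >= 0.5 reads/codon;
UTR pseudo-codons are scored against the same CDS-derived baseline so
that UTR pauses stay comparable to coding ones.

Note a hard ceiling of this statistic: a single spiked codon on an
n-codon CDS cannot exceed z = sqrt(n - 1), so transcripts shorter than
~100 codons can never yield a z >= 10 pause regardless of amplification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import pandas as pd

from .annotation import Region, TranscriptomeModel
from .footprints import AsiteProfile
from .stats import rank_sum_test

log = logging.getLogger(__name__)

Z_THRESHOLD = 10.0
COVERAGE_THRESHOLD = 0.5  # reads per CDS codon, inclusive
START_MASK_P_CODONS = (-3, 0, 1, 2, 3, 4)  # P-site codons relative to start
STOP_MASK_P_CODONS = (-1, -2)  # P-site codons relative to the stop codon


@dataclass
class PauseCandidate:
    transcript_id: str
    codon_index: int
    codon: str  # A-site codon 3-mer
    z: float
    mean_coverage: float  # transcript CDS mean, reads/codon
    sample_id: str
    region: Region


def pause_scores(
    profile: AsiteProfile,
    model: TranscriptomeModel,
    z_threshold: float = Z_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    sample_sd: bool = False,
    utr_in_baseline: bool = False,
) -> list[PauseCandidate]:
    """Score every codon of a transcript profile and emit candidates.

    ``sample_sd`` switches sigma to the n-1 (sample) convention;
    ``utr_in_baseline`` includes UTR pseudo-codons in mu/sigma.  Both
    default to the documented convention (population SD, CDS-only
    baseline).  A zero sigma or a sub-threshold mean emits nothing.
    """
    if profile.counts.size == 0:
        return []
    baseline = profile.counts if utr_in_baseline else profile.cds_counts
    mu_cds = float(profile.cds_counts.mean())
    mu = float(baseline.mean())
    sigma = float(baseline.std(ddof=1 if sample_sd else 0))
    if mu_cds < coverage_threshold or sigma == 0.0:
        return []
    z = (profile.counts - mu) / sigma
    tr = model.transcripts[profile.transcript_id]
    out = []
    for codon_idx in np.flatnonzero(z >= z_threshold):
        codon_idx = int(codon_idx)
        out.append(
            PauseCandidate(
                transcript_id=profile.transcript_id,
                codon_index=codon_idx,
                codon=model.codon_seq(profile.transcript_id, codon_idx),
                z=float(z[codon_idx]),
                mean_coverage=mu_cds,
                sample_id=profile.sample_id,
                region=model.classify_region(
                    profile.transcript_id, tr.codon_start(codon_idx)
                ),
            )
        )
    return out


def _gene_masked_loci(model: TranscriptomeModel, gene_id: str) -> set[tuple[str, int]]:
    """Genomic first-nt coordinates of P-site codons excluded near start
    and stop codons, pooled over every coding isoform of the gene."""
    masked: set[tuple[str, int]] = set()
    for tid in model.genes[gene_id]:
        tr = model.transcripts[tid]
        if not tr.is_coding or not tr.analyzable:
            continue
        codons = [tr.cds_first_codon + d for d in START_MASK_P_CODONS]
        codons += [tr.cds_last_codon + d for d in STOP_MASK_P_CODONS]
        for c in codons:
            if 0 <= c < tr.n_codons:
                chrom, gpos, _ = model.genomic_codon_key(tid, c)
                masked.add((chrom, gpos))
    return masked


def mask_start_stop(
    candidates: list[PauseCandidate], model: TranscriptomeModel
) -> list[PauseCandidate]:
    """Drop candidates whose P-site codon (A-site codon - 1) coincides, in
    any isoform of the same gene, with a start-relative codon in
    {-3,0,1,2,3,4} or a stop-relative codon in {-1,-2}.  Identity is by
    genomic coordinate of the codon's first nucleotide."""
    cache: dict[str, set[tuple[str, int]]] = {}
    kept = []
    for cand in candidates:
        tr = model.transcripts[cand.transcript_id]
        gene = tr.gene_id
        if gene not in cache:
            cache[gene] = _gene_masked_loci(model, gene)
        p_codon = cand.codon_index - 1
        if p_codon < 0:
            kept.append(cand)
            continue
        chrom, gpos, _ = model.genomic_codon_key(cand.transcript_id, p_codon)
        if (chrom, gpos) not in cache[gene]:
            kept.append(cand)
    return kept


@dataclass
class GenePause:
    """A gene-level pause locus: genomically identical A-site codons
    collapsed across isoforms, with per-sample mean scores."""

    gene_id: str
    chrom: str
    pos: int  # genomic coordinate of the A-site codon's first nt
    strand: str
    scores: dict[str, float] = field(default_factory=dict)  # sample -> mean z
    regions: set[Region] = field(default_factory=set)
    transcript_ids: set[str] = field(default_factory=set)
    replicate_presence: dict[str, tuple[bool, ...]] = field(default_factory=dict)
    classification: str | None = None

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.gene_id, self.chrom, self.pos, self.strand)


def collapse_to_gene(
    candidates: list[PauseCandidate], model: TranscriptomeModel
) -> list[GenePause]:
    """Merge candidates sharing (gene, chromosome, genomic A-site, strand).

    The per-sample score is the arithmetic mean of z over the transcripts
    reporting the pause in that sample; regions are the union over
    isoforms.  Identical loci claimed by different genes stay separate.
    """
    per_locus: dict[tuple[str, str, int, str], dict] = {}
    for cand in candidates:
        chrom, gpos, strand = model.genomic_codon_key(
            cand.transcript_id, cand.codon_index
        )
        gene = model.gene_of(cand.transcript_id)
        key = (gene, chrom, gpos, strand)
        entry = per_locus.setdefault(
            key, {"z": {}, "regions": set(), "tids": set()}
        )
        entry["z"].setdefault(cand.sample_id, []).append(cand.z)
        entry["regions"].add(cand.region)
        entry["tids"].add(cand.transcript_id)
    chrom_pos_genes: dict[tuple[str, int], set[str]] = {}
    for gene, chrom, gpos, _ in per_locus:
        chrom_pos_genes.setdefault((chrom, gpos), set()).add(gene)
    for (chrom, gpos), genes in chrom_pos_genes.items():
        if len(genes) > 1:
            log.info(
                "locus %s:%d claimed by multiple genes (%s); kept separately",
                chrom, gpos, ",".join(sorted(genes)),
            )
    out = []
    for (gene, chrom, gpos, strand), entry in sorted(per_locus.items()):
        out.append(
            GenePause(
                gene_id=gene,
                chrom=chrom,
                pos=gpos,
                strand=strand,
                scores={s: float(np.mean(zs)) for s, zs in sorted(entry["z"].items())},
                regions=entry["regions"],
                transcript_ids=entry["tids"],
            )
        )
    return out


def replicate_filter(
    pauses: list[GenePause], design: dict[str, list[str]]
) -> dict[str, list[GenePause]]:
    """Keep, per genotype, only loci detected in every replicate.

    ``design`` maps genotype -> ordered sample ids.  Presence in a sample
    means the locus carried a candidate (z above threshold, post-masking)
    there.  The per-genotype presence bit-set is recorded on each locus.
    """
    for genotype, samples in design.items():
        if not samples:
            raise ValueError(f"genotype {genotype!r} has no samples")
    surviving: dict[str, list[GenePause]] = {g: [] for g in design}
    for pause in pauses:
        for genotype, samples in design.items():
            presence = tuple(s in pause.scores for s in samples)
            pause.replicate_presence[genotype] = presence
            if all(presence):
                surviving[genotype].append(pause)
    return surviving


@dataclass
class PauseClassification:
    control_only: set[tuple]
    shared: set[tuple]
    mutant_only: set[tuple]
    genes: dict[str, set[str]]  # class -> distinct gene ids

    def counts(self) -> dict[str, int]:
        return {
            "control_only": len(self.control_only),
            "shared": len(self.shared),
            "mutant_only": len(self.mutant_only),
        }


def classify_pauses(
    control: list[GenePause], mutant: list[GenePause]
) -> PauseClassification:
    """Partition loci into control-only / shared / mutant-only and record
    the distinct genes each class maps to."""
    ckeys = {p.key for p in control}
    mkeys = {p.key for p in mutant}
    shared = ckeys & mkeys
    c_only = ckeys - mkeys
    m_only = mkeys - ckeys
    by_key = {p.key: p for p in control + mutant}
    for key in c_only:
        by_key[key].classification = "control_only"
    for key in shared:
        by_key[key].classification = "shared"
    for key in m_only:
        by_key[key].classification = "mutant_only"
    genes = {
        "control_only": {k[0] for k in c_only},
        "shared": {k[0] for k in shared},
        "mutant_only": {k[0] for k in m_only},
    }
    return PauseClassification(c_only, shared, m_only, genes)


def compare_pause_scores(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two score samples
    (exact by enumeration when both n <= 8, tie-corrected normal
    approximation otherwise)."""
    return rank_sum_test(scores_a, scores_b)


def codon_occupancy(
    profiles: dict[str, AsiteProfile],
    model: TranscriptomeModel,
    pseudocount: float = 0.5,
    coverage_threshold: float = COVERAGE_THRESHOLD,
    min_transcripts: int = 3,
) -> pd.DataFrame:
    """Observed/expected A-site occupancy per codon across transcripts.

    For each transcript passing the coverage threshold, the expected
    reads on a codon are total CDS reads x (codon occurrences / CDS
    codons).  The reported ratio is plain observed/expected; the test
    statistic is log2((observed + pc) / expected) — the half-count on
    the observed side both avoids log 0 and corrects the Jensen bias of
    the log at Poisson-scale counts, keeping the per-codon t-test
    calibrated under a uniform null.  Each codon is tested two-sided
    against 0 across transcripts and BH-corrected.

    Returns a DataFrame indexed by codon with columns ``n_transcripts``,
    ``mean_ratio``, ``mean_log2_ratio``, ``t``, ``p``, ``q``, sorted by p.
    """
    ratios: dict[str, list[float]] = {}
    plain: dict[str, list[float]] = {}
    for tid, profile in sorted(profiles.items()):
        tr = model.transcripts[tid]
        cds = profile.cds_counts
        total = float(cds.sum())
        n_cds = cds.size
        if n_cds == 0 or total / n_cds < coverage_threshold:
            continue
        first = tr.cds_first_codon
        codon_positions: dict[str, list[int]] = {}
        for i in range(n_cds):
            codon_positions.setdefault(model.codon_seq(tid, first + i), []).append(i)
        for codon, positions in codon_positions.items():
            observed = float(cds[positions].sum())
            expected = total * len(positions) / n_cds
            ratios.setdefault(codon, []).append(
                float(np.log2((observed + pseudocount) / expected))
            )
            plain.setdefault(codon, []).append(observed / expected)
    rows = []
    for codon in sorted(ratios):
        vals = np.array(ratios[codon])
        if vals.size < min_transcripts or vals.size < 2:
            continue
        if vals.std(ddof=1) == 0.0:
            # constant log-ratios: no evidence unless the constant is off 0
            t, p = (0.0, 1.0) if vals.mean() == 0 else (np.sign(vals.mean()) * np.inf, 0.0)
        else:
            t, p = sps.ttest_1samp(vals, 0.0)
        rows.append(
            (codon, vals.size, float(np.mean(plain[codon])), float(vals.mean()),
             float(t), float(p))
        )
    if not rows:
        return pd.DataFrame(
            columns=["n_transcripts", "mean_ratio", "mean_log2_ratio", "t", "p", "q"]
        )
    df = pd.DataFrame(
        rows,
        columns=["codon", "n_transcripts", "mean_ratio", "mean_log2_ratio", "t", "p"],
    ).set_index("codon")
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("p")


def assign_unique_transcript(
    pause: GenePause, model: TranscriptomeModel
) -> str | None:
    """The single isoform whose exons contain the pause locus, or None
    when zero or several isoforms overlap it (ambiguous)."""
    hits = []
    for tid in model.genes[pause.gene_id]:
        tr = model.transcripts[tid]
        if tr.chrom != pause.chrom:
            continue
        if any(s <= pause.pos < e for s, e in tr.exons):
            hits.append(tid)
    return hits[0] if len(hits) == 1 else None
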