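"""Counting, normalization, TE and the gene-set shift layer."""

import numpy as np
import pandas as pd
import pytest

from ribopause.footprints import FootprintAlignment, OffsetTable
from ribopause.stats import rank_sum_test
from ribopause.translatome import (
    CountMatrix,
    attach_size_factors,
    compute_te,
    condition_correlation,
    count_features,
    drop_histones,
    geneset_shift_test,
    opposing_regulation,
    pausing_vs_expression,
    size_factors,
)


def _samples(ids, assay="RPF"):
    return pd.DataFrame(
        {"assay": assay, "genotype": "control", "replicate": range(1, len(ids) + 1)},
        index=pd.Index(ids, name="sample_id"),
    )


def test_cds_counting_uses_asite_and_skips_utr_reads(toy_model):
    offsets = OffsetTable({28: 12})
    tr = toy_model.transcripts["a1"]
    in_cds = FootprintAlignment("r1", "a1", tr.cds_start - 15 + 30, 28, "s1")
    in_utr3 = FootprintAlignment("r2", "a1", tr.cds_end + 2, 28, "s1")
    matrix = count_features(
        {"s1": [in_cds, in_utr3]}, toy_model, _samples(["s1"]), offsets=offsets
    )
    assert matrix.counts.loc["geneA", "s1"] == 1
    assert matrix.counts.loc["geneB", "s1"] == 0


def test_exon_counting_uses_fragment_midpoint(toy_model):
    aln = FootprintAlignment("r1", "b1", 10, 30, "s1")
    matrix = count_features(
        {"s1": [aln]}, toy_model, _samples(["s1"], assay="RNA"), feature="exon"
    )
    assert matrix.counts.loc["geneB", "s1"] == 1


def test_read_overlapping_two_genes_is_ambiguous():
    """Two genes sharing CDS territory: the read counts for neither."""
    from ribopause.annotation import TranscriptRecord, TranscriptomeModel

    t1 = TranscriptRecord("x1", "gX", "chr1", "+", [(100, 400)], cds_start=30, cds_end=240)
    t2 = TranscriptRecord("y1", "gY", "chr1", "+", [(150, 450)], cds_start=0, cds_end=210)
    model = TranscriptomeModel(
        genes={"gX": ["x1"], "gY": ["y1"]},
        transcripts={"x1": t1, "y1": t2},
        sequences={"x1": "A" * 300, "y1": "A" * 300},
    )
    offsets = OffsetTable({28: 12})
    aln = FootprintAlignment("r", "x1", 85, 28, "s1")  # A-site at 100 -> chr1:200
    matrix = count_features({"s1": [aln]}, model, _samples(["s1"]), offsets=offsets)
    assert matrix.counts["s1"].sum() == 0


def test_counts_match_simulator_truth(small_sim, small_design):
    """Gene counts from A-site assignment equal the per-read manifest
    truth for reads whose A-site falls in the CDS."""
    sample = "mutant_rep3"
    offsets = OffsetTable(dict(small_sim.config.p_offsets))
    samples = _samples([sample])
    matrix = count_features(
        {sample: small_sim.footprint_alignments(sample)},
        small_sim.model,
        samples,
        offsets=offsets,
    )
    truth = {}
    for read in small_sim.reads(sample):
        if read.unmapped:
            continue
        tr = small_sim.model.transcripts[read.transcript_id]
        a_pos = read.five_prime_pos + offsets.a_offset(read.length)
        codon = tr.codon_index(a_pos) if a_pos >= tr.frame_anchor else None
        if codon is not None and tr.cds_first_codon <= codon <= tr.cds_last_codon:
            truth[tr.gene_id] = truth.get(tr.gene_id, 0) + 1
    got = matrix.counts[sample]
    for gene in small_sim.model.genes:
        assert got[gene] == truth.get(gene, 0)


def test_histone_prefixes_are_case_sensitive():
    counts = pd.DataFrame(
        {"s1": [5, 5, 5, 5]},
        index=["Hist1h1a", "H2afz", "Hba-a1", "H3f3a"],
    )
    matrix = CountMatrix(counts=counts, samples=_samples(["s1"]))
    kept = drop_histones(matrix).counts.index
    assert list(kept) == ["Hba-a1"]


def test_size_factors_identity_and_scaling():
    counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]}, index=list("xyz"))
    assert np.allclose(size_factors(counts), 1.0)
    counts2 = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]}, index=list("xyz"))
    f = size_factors(counts2)
    assert f["b"] / f["a"] == pytest.approx(2.0)
    with pytest.raises(ValueError):
        size_factors(pd.DataFrame({"a": [0, 1], "b": [1, 0]}))


def bruteforce_size_factors(counts: pd.DataFrame) -> dict:
    """Independent median-of-ratios oracle with explicit loops."""
    import math
    import statistics

    usable = [g for g in counts.index if all(counts.loc[g] > 0)]
    geo = {
        g: math.exp(sum(math.log(c) for c in counts.loc[g]) / counts.shape[1])
        for g in usable
    }
    raw = {
        s: statistics.median(counts.loc[g, s] / geo[g] for g in usable)
        for s in counts.columns
    }
    scale = math.exp(sum(math.log(v) for v in raw.values()) / len(raw))
    return {s: v / scale for s, v in raw.items()}


def test_size_factors_match_bruteforce_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        counts = pd.DataFrame(
            rng.poisson(30, size=(40, 4)),
            columns=list("abcd"),
            index=[f"g{i}" for i in range(40)],
        )
        got = size_factors(counts)
        oracle = bruteforce_size_factors(counts)
        for s in counts.columns:
            assert got[s] == pytest.approx(oracle[s], abs=1e-9)


def test_normalization_idempotence():
    rng = np.random.default_rng(8)
    counts = pd.DataFrame(
        rng.poisson(50, size=(60, 3)) + 1, columns=list("abc")
    ) * np.array([1.0, 2.0, 0.5])
    f = size_factors(counts)
    again = size_factors(counts / f)
    assert np.allclose(again, 1.0, atol=1e-9)


def _te_matrix(rpf_mut_scale=1.0):
    genes = [f"g{i}" for i in range(8)]
    rng = np.random.default_rng(9)
    base = rng.integers(100, 200, len(genes)).astype(float)
    cols, meta = {}, []
    for geno in ("control", "mutant"):
        for r in (1, 2):
            scale = rpf_mut_scale if geno == "mutant" else 1.0
            cols[f"{geno}_{r}"] = (base * scale).astype(int)
            cols[f"{geno}_{r}_rna"] = base.astype(int)
            meta.append((f"{geno}_{r}", "RPF", geno, r))
            meta.append((f"{geno}_{r}_rna", "RNA", geno, r))
    samples = pd.DataFrame(
        meta, columns=["sample_id", "assay", "genotype", "replicate"]
    ).set_index("sample_id")
    counts = pd.DataFrame(cols, index=genes)
    return CountMatrix(counts[list(samples.index)], samples)


def test_te_zero_when_rpf_equals_rna_and_plus_one_when_doubled():
    te = compute_te(_te_matrix(), "control", "mutant")
    assert np.allclose(te["log2_te_control"], 0.0, atol=0.02)
    assert np.allclose(te["delta_log2_te"], 0.0, atol=0.02)
    te2 = compute_te(_te_matrix(rpf_mut_scale=2.0), "control", "mutant")
    # normalization absorbs a uniform doubling of the mutant RPF library,
    # so TE is invariant to library scaling ...
    assert np.allclose(te2["delta_log2_te"], 0.0, atol=0.02)
    # ... but an unnormalized matrix shows the raw +1 shift
    m = _te_matrix(rpf_mut_scale=2.0)
    m.size_factors = pd.Series(1.0, index=m.samples.index)
    te3 = compute_te(m, "control", "mutant")
    assert np.allclose(te3["delta_log2_te"], 1.0, atol=0.02)


def test_te_requires_both_assays_per_genotype():
    m = _te_matrix()
    rpf_only = CountMatrix(
        m.counts[[c for c in m.counts if "rna" not in c]],
        m.samples[m.samples["assay"] == "RPF"],
    )
    with pytest.raises(ValueError, match="RNA"):
        compute_te(rpf_only, "control", "mutant")


def test_geneset_shift_reduces_to_rank_sum(toy_model):
    rng = np.random.default_rng(10)
    values = pd.Series(rng.normal(0, 1, 50), index=[f"g{i}" for i in range(50)])
    members = [f"g{i}" for i in range(8)]
    res = geneset_shift_test(values, members)
    stat, p = rank_sum_test(
        values.loc[members].to_numpy(), values.drop(index=members).to_numpy()
    )
    assert (res.statistic, res.p) == (stat, p)
    with pytest.raises(ValueError, match="background"):
        geneset_shift_test(values, list(values.index))
    with pytest.raises(ValueError, match="fewer"):
        geneset_shift_test(values, members[:3])


def test_injected_shift_detected_with_direction():
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(600)]
    values = pd.Series(rng.normal(0, 1, 600), index=genes)
    values.iloc[:60] += 0.5
    res = geneset_shift_test(values, genes[:60])
    assert res.p < 0.01 and res.direction == 1


def test_opposing_regulation_buffering_and_null():
    rng = np.random.default_rng(12)
    genes = [f"g{i}" for i in range(800)]
    mrna = pd.Series(rng.normal(0, 1, 800), index=genes)
    te_buffered = -0.8 * mrna + pd.Series(rng.normal(0, 0.3, 800), index=genes)
    res = opposing_regulation(mrna, te_buffered)
    assert res.up_mrna_test.p < 0.01 and res.up_mrna_test.direction == -1
    assert res.down_mrna_test.direction == 1
    assert len(res.up_mrna_down_te) > 0
    # unchanged genes produce empty opposing lists
    zero = pd.Series(0.0, index=genes)
    res0 = opposing_regulation(zero, zero)
    assert res0.up_mrna_down_te == [] and res0.down_mrna_up_te == []
    with pytest.raises(ValueError):
        opposing_regulation(mrna, te_buffered.iloc[:10])


def test_condition_correlation_linearity_and_oracle():
    a = pd.Series([1.0, 2.0, 4.0, 8.0, 16.0], index=list("abcde"))
    assert condition_correlation(a, 2 * a) == pytest.approx(1.0)
    b = pd.Series([3.0, 1.0, 4.0, 1.0, 5.0], index=list("abcde"))
    av, bv = a.to_numpy(), b.to_numpy()
    r_hand = ((av * bv).mean() - av.mean() * bv.mean()) / (av.std() * bv.std())
    assert condition_correlation(a, b) == pytest.approx(r_hand, abs=1e-12)
    with pytest.raises(ValueError):
        condition_correlation(a.iloc[:2], b.iloc[:2])


def test_pausing_vs_expression_detects_coupling_and_skips_small_classes():
    rng = np.random.default_rng(13)
    genes = [f"g{i}" for i in range(400)]
    changes = pd.Series(rng.normal(0, 0.5, 400), index=genes)
    pausing = set(genes[:40])
    changes[list(pausing)] -= 0.8  # mutant-specific pausing genes translate less
    out = pausing_vs_expression(
        {"mutant_only": pausing, "control_only": set(genes[40:42])}, changes
    )
    assert out["mutant_only"].p < 0.01 and out["mutant_only"].direction == -1
    assert "control_only" not in out  # 2 genes: skipped
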