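"""Pause scoring, masking, collapsing, replicate logic, classification
and codon occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribopause.annotation import Region
from ribopause.footprints import AsiteProfile, OffsetTable, build_profiles, calibrate_offsets
from ribopause.pausing import (
    GenePause,
    PauseCandidate,
    assign_unique_transcript,
    classify_pauses,
    codon_occupancy,
    collapse_to_gene,
    mask_start_stop,
    pause_scores,
    replicate_filter,
)
from ribopause.scenarios import codon_design


def brute_force_z(counts, cds_range, codon):
    """Independent two-pass mean/SD oracle over CDS codons."""
    first, last = cds_range
    cds = [float(c) for c in counts[first : last + 1]]
    mu = sum(cds) / len(cds)
    sd = (sum((c - mu) ** 2 for c in cds) / len(cds)) ** 0.5
    return (counts[codon] - mu) / sd


def make_profile(model, tid, counts, sample="s1"):
    tr = model.transcripts[tid]
    return AsiteProfile(
        transcript_id=tid,
        sample_id=sample,
        counts=np.asarray(counts, dtype=np.int64),
        cds_codon_range=(tr.cds_first_codon, tr.cds_last_codon),
    )


def test_uniform_profile_has_zero_sd_and_no_candidates(toy_model):
    tr = toy_model.transcripts["a1"]
    profile = make_profile(toy_model, "a1", [3] * tr.n_codons)
    assert pause_scores(profile, toy_model) == []


def test_spike_z_matches_bruteforce_oracle(toy_model):
    tr = toy_model.transcripts["a1"]
    counts = [1] * tr.n_codons
    spike = tr.cds_first_codon + 15
    counts[spike] = 60
    profile = make_profile(toy_model, "a1", counts)
    z_expected = brute_force_z(np.array(counts), profile.cds_codon_range, spike)
    # a single spike on an n-codon CDS is bounded by z = sqrt(n-1), so a
    # 30-codon CDS cannot reach the default threshold of 10 ...
    assert z_expected < 10
    assert pause_scores(profile, toy_model) == []
    # ... but at a permissive threshold the candidate and its z match the
    # independent two-pass oracle
    cands = pause_scores(profile, toy_model, z_threshold=3.0)
    assert [c.codon_index for c in cands] == [spike]
    assert cands[0].z == pytest.approx(z_expected, abs=1e-9)
    assert cands[0].region is Region.CDS


def test_low_coverage_spike_is_suppressed(toy_model):
    """Transcript mean below 0.5 reads/codon never yields a pause."""
    tr = toy_model.transcripts["a1"]
    counts = [0] * tr.n_codons
    counts[tr.cds_first_codon + 10] = int(0.4 * (tr.cds_last_codon - tr.cds_first_codon + 1))
    profile = make_profile(toy_model, "a1", counts)
    assert profile.cds_counts.mean() < 0.5
    assert pause_scores(profile, toy_model) == []


def test_utr_candidates_scored_against_cds_baseline(toy_model):
    tr = toy_model.transcripts["a1"]
    counts = [0] * tr.n_codons
    for i, c in enumerate(range(tr.cds_first_codon, tr.cds_last_codon + 1)):
        counts[c] = 1 + i % 3  # non-degenerate CDS baseline
    utr_codon = tr.cds_last_codon + 3  # 3'UTR pseudo-codon
    counts[utr_codon] = 80
    profile = make_profile(toy_model, "a1", counts)
    cands = pause_scores(profile, toy_model)
    assert [c.codon_index for c in cands] == [utr_codon]
    assert cands[0].region is Region.THREE_PRIME_UTR
    # baseline excludes the UTR spike: mu/sigma from CDS codons only
    assert cands[0].z == pytest.approx(
        brute_force_z(np.array(counts), profile.cds_codon_range, utr_codon), abs=1e-9
    )


def _candidate(model, tid, codon, z=15.0, sample="s1"):
    tr = model.transcripts[tid]
    return PauseCandidate(
        transcript_id=tid,
        codon_index=codon,
        codon=model.codon_seq(tid, codon),
        z=z,
        mean_coverage=2.0,
        sample_id=sample,
        region=model.classify_region(tid, tr.codon_start(codon)),
    )


def test_mask_removes_start_neighbourhood_same_isoform(toy_model):
    tr = toy_model.transcripts["a1"]
    # A-site codon = start+3 => P-site codon = start+2: masked
    cand = _candidate(toy_model, "a1", tr.cds_first_codon + 3)
    assert mask_start_stop([cand], toy_model) == []
    # P-site at start-relative codon 5 (A-site at +6): retained
    keep = _candidate(toy_model, "a1", tr.cds_first_codon + 6)
    assert mask_start_stop([keep], toy_model) == [keep]


def test_mask_applies_across_isoforms_of_the_gene(toy_model):
    """a1 and a2 share CDS coordinates; a candidate whose P-site codon
    is stop-1 in a2 is removed even when reported on a1."""
    tr = toy_model.transcripts["a1"]
    cand = _candidate(toy_model, "a1", tr.cds_last_codon)  # P-site = stop-1
    assert mask_start_stop([cand], toy_model) == []


def test_collapse_averages_scores_and_unions_regions(toy_model):
    tr1 = toy_model.transcripts["a1"]
    c = tr1.cds_first_codon + 10
    cand1 = _candidate(toy_model, "a1", c, z=12.0)
    cand2 = _candidate(toy_model, "a2", c, z=18.0)
    merged = collapse_to_gene([cand1, cand2], toy_model)
    assert len(merged) == 1
    assert merged[0].scores["s1"] == pytest.approx(15.0)
    assert merged[0].transcript_ids == {"a1", "a2"}
    single = collapse_to_gene([cand1], toy_model)
    assert single[0].scores["s1"] == pytest.approx(12.0)


def test_collapse_reports_all_regions_of_genomically_identical_pauses(toy_model):
    """The same genomic locus can be CDS in one isoform and 3'UTR in
    another; both labels are reported."""
    tr = toy_model.transcripts["a1"]
    utr_codon = tr.cds_last_codon + 2
    c1 = _candidate(toy_model, "a1", utr_codon)
    c2 = _candidate(toy_model, "a2", utr_codon)
    # same transcript coordinates on both isoforms -> same genomic locus
    merged = collapse_to_gene([c1, c2], toy_model)
    assert len(merged) == 1
    assert Region.THREE_PRIME_UTR in merged[0].regions


def _locus(gene, pos, samples):
    return GenePause(
        gene_id=gene, chrom="chr1", pos=pos, strand="+",
        scores={s: 12.0 for s in samples},
    )


def test_replicate_filter_requires_every_replicate():
    design = {"control": ["c1", "c2", "c3"], "mutant": ["m1", "m2", "m3"]}
    full = _locus("g", 100, ["m1", "m2", "m3"])
    partial = _locus("g", 200, ["m1", "m2"])
    out = replicate_filter([full, partial], design)
    assert out["mutant"] == [full]
    assert out["control"] == []
    assert partial.replicate_presence["mutant"] == (True, True, False)
    with pytest.raises(ValueError):
        replicate_filter([], {"control": []})


@settings(max_examples=50, derandomize=True)
@given(presence=st.lists(st.tuples(*[st.booleans()] * 6), min_size=1, max_size=40))
def test_replicate_filter_equals_set_intersection_oracle(presence):
    """Random presence matrices: survivors per genotype equal the brute
    force intersection of per-replicate detection sets."""
    design = {"control": ["c1", "c2", "c3"], "mutant": ["m1", "m2", "m3"]}
    samples = design["control"] + design["mutant"]
    loci = []
    for i, bits in enumerate(presence):
        present = [s for s, b in zip(samples, bits) if b]
        if present:
            loci.append(_locus("g", i, present))
    out = replicate_filter(loci, design)
    for genotype, ids in design.items():
        expected = set.intersection(
            *[{l.pos for l in loci if s in l.scores} for s in ids]
        )
        assert {l.pos for l in out[genotype]} == expected


def test_classification_is_a_partition():
    a, b, c = (_locus("g", p, ["c1"]) for p in (1, 2, 3))
    b2 = _locus("g", 2, ["m1"])
    c2 = _locus("g", 3, ["m1"])
    d = _locus("g", 4, ["m1"])
    cls = classify_pauses([a, b], [b2, c2, d][0:1] + [d])
    assert cls.control_only == {a.key}
    assert cls.shared == {b.key}
    assert cls.mutant_only == {d.key}
    empty = classify_pauses([a, b], [])
    assert empty.mutant_only == set() and empty.control_only == {a.key, b.key}


@settings(max_examples=50, derandomize=True)
@given(
    ctrl=st.sets(st.integers(0, 30)),
    mut=st.sets(st.integers(0, 30)),
)
def test_classification_counts_partition_the_union(ctrl, mut):
    control = [_locus("g", p, ["c1"]) for p in ctrl]
    mutant = [_locus("g", p, ["m1"]) for p in mut]
    cls = classify_pauses(control, mutant)
    total = len(cls.control_only) + len(cls.shared) + len(cls.mutant_only)
    assert total == len(ctrl | mut)


def test_assign_unique_transcript_uses_exon_overlap(toy_model):
    # locus in the 3'UTR extension unique to a2
    pause_unique = GenePause("geneA", "chr1", 1160, "+")
    assert assign_unique_transcript(pause_unique, toy_model) == "a2"
    # locus in the shared exon region: ambiguous
    pause_shared = GenePause("geneA", "chr1", 1050, "+")
    assert assign_unique_transcript(pause_shared, toy_model) is None


def test_unique_assignment_fraction_matches_bruteforce_overlap(small_sim):
    """Across random loci, uniqueness equals a per-base isoform-overlap
    count."""
    model = small_sim.model
    rng = np.random.default_rng(3)
    for gid in sorted(model.genes):
        tids = model.genes[gid]
        tr = model.transcripts[tids[0]]
        for _ in range(5):
            pos = int(rng.integers(tr.exons[0][0] - 10, max(e for _, e in tr.exons) + 10))
            n_overlap = sum(
                any(s <= pos < e for s, e in model.transcripts[t].exons) for t in tids
            )
            got = assign_unique_transcript(GenePause(gid, tr.chrom, pos, tr.strand), model)
            assert (got is not None) == (n_overlap == 1)


def test_exact_expectation_gives_unit_ratio(toy_model):
    """A transcript whose counts are perfectly uniform has ratio 1 (log2
    ratio 0) for every codon."""
    profiles = {}
    for tid in ("a1", "a2"):
        tr = toy_model.transcripts[tid]
        counts = [0] * tr.n_codons
        for c in range(tr.cds_first_codon, tr.cds_last_codon + 1):
            counts[c] = 2
        profiles[tid] = make_profile(toy_model, tid, counts)
    table = codon_occupancy(profiles, toy_model, min_transcripts=2)
    assert np.allclose(table["mean_ratio"], 1.0, atol=1e-12)


def test_injected_dwell_ranks_target_codon_first():
    sim = codon_design(13, dwell={"AGA": 3.0}, n_genes=60)
    sample = sim.config.sample_ids()[0]
    alns = sim.footprint_alignments(sample)
    offsets = OffsetTable(dict(sim.config.p_offsets))
    profiles = build_profiles(alns, offsets, sim.model, sample)
    table = codon_occupancy(profiles, sim.model)
    assert table.index[0] == "AGA"
    assert table["q"].iloc[0] <= 0.05
    assert table.loc["AGA", "mean_log2_ratio"] > 1.0
    # q-values are monotone in p
    assert (table.sort_values("p")["q"].diff().dropna() >= -1e-12).all()
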