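"""Footprint ingestion, offset calibration, A-site profiles, metagene
and the poly(A) suffix scan."""

import numpy as np
import pytest

from ribopause.annotation import UnsupportedTranscriptError
from ribopause.footprints import (
    FootprintAlignment,
    OffsetTable,
    build_asite_profile,
    build_profiles,
    calibrate_offsets,
    ingest_alignments,
    metagene,
    polyA_suffix_scan,
)
from ribopause.scenarios import codon_design


def _write_sam(path, reads):
    lines = ["@HD\tVN:1.6", "@SQ\tSN:tx\tLN:500"]
    for name, flag, pos, cigar, seq in reads:
        lines.append(f"{name}\t{flag}\t tx\t{pos}\t255\t{cigar}\t*\t0\t0\t{seq}\t*".replace(" ", ""))
    path.write_text("\n".join(lines) + "\n")


def test_length_filter_keeps_only_27_to_34(tmp_path):
    sam = tmp_path / "lens.sam"
    _write_sam(
        sam,
        [
            ("r25", 0, 1, "25M", "A" * 25),
            ("r27", 0, 1, "27M", "A" * 27),
            ("r34", 0, 1, "34M", "A" * 34),
            ("r36", 0, 1, "36M", "A" * 36),
            ("r30sec", 256, 1, "30M", "A" * 30),  # secondary: dropped
        ],
    )
    alns = ingest_alignments(sam, "s1")
    assert sorted(a.read_id for a in alns) == ["r27", "r34"]
    assert all(27 <= a.length <= 34 for a in alns)


def test_empty_file_yields_empty_list(tmp_path):
    sam = tmp_path / "empty.sam"
    sam.write_text("@HD\tVN:1.6\n@SQ\tSN:tx\tLN:500\n")
    assert ingest_alignments(sam, "s1") == []


def test_simulated_file_retention_matches_manifest(tmp_path, small_sim):
    """Every simulated footprint is 27-34 nt, so retention is total."""
    sample = "control_rep1"
    path = tmp_path / "sim.sam"
    small_sim.write_sam(sample, path, "transcript")
    alns = ingest_alignments(path, sample)
    expected = sum(1 for r in small_sim.reads(sample) if not r.unmapped)
    assert len(alns) == expected


def test_offset_calibration_recovers_simulator_truth(small_sim):
    pooled = [
        a
        for s in small_sim.config.sample_ids()
        for a in small_sim.footprint_alignments(s)
    ]
    table = calibrate_offsets(pooled, small_sim.model)
    truth = dict(small_sim.config.p_offsets)
    per_len = {}
    for a in pooled:
        per_len[a.length] = per_len.get(a.length, 0) + 1
    for length, true_off in truth.items():
        if per_len.get(length, 0) >= 500:
            assert table.p_offset(length) == true_off


def test_offset_tie_breaks_small_and_sparse_falls_back(toy_model):
    tr = toy_model.transcripts["a1"]
    # 200 reads whose 5' ends put the P-site on the start codon at offset
    # 13, and 200 at offset 15: equal peaks, smaller offset wins
    alns = []
    for i in range(200):
        for off in (13, 15):
            alns.append(
                FootprintAlignment(
                    read_id=f"r{i}o{off}", ref="a1",
                    five_prime_pos=tr.cds_start - off, length=28, sample_id="s",
                )
            )
    table = calibrate_offsets(alns, toy_model)
    assert table.p_offset(28) == 13
    assert table.p_offset(31) == 12  # no reads of this length: default


def test_asite_assignment_and_discard_tally(toy_model):
    offsets = OffsetTable({n: 12 for n in range(27, 35)})
    tr = toy_model.transcripts["a1"]
    inside = FootprintAlignment("ok", "a1", 0, 28, "s")  # A-site at nt 15
    past_end = FootprintAlignment("off", "a1", tr.length - 10, 28, "s")
    profile = build_asite_profile([inside, past_end], offsets, toy_model, "a1", "s")
    expected_codon = (15 - tr.frame_anchor) // 3
    assert profile.counts[expected_codon] == 1
    assert profile.counts.sum() == 1
    assert profile.n_discarded == 1


def test_count_conservation_across_transcripts(small_sim):
    """Sum of profile counts plus discards equals retained alignments on
    analyzable transcripts."""
    sample = "control_rep2"
    alns = small_sim.footprint_alignments(sample)
    offsets = OffsetTable(dict(small_sim.config.p_offsets))
    profiles = build_profiles(alns, offsets, small_sim.model, sample)
    total = sum(p.counts.sum() + p.n_discarded for p in profiles.values())
    analyzable = {
        tid
        for tid, tr in small_sim.model.transcripts.items()
        if tr.is_coding and tr.analyzable
    }
    assert total == sum(1 for a in alns if a.ref in analyzable)


def test_unanalyzable_transcript_raises(toy_model):
    offsets = OffsetTable({28: 12})
    with pytest.raises(KeyError):
        build_asite_profile([], offsets, toy_model, "nope", "s")


@pytest.fixture(scope="module")
def uniform_metagene():
    sim = codon_design(9, n_genes=120)
    sample = sim.config.sample_ids()[0]
    alns = sim.footprint_alignments(sample)
    offsets = OffsetTable(dict(sim.config.p_offsets))
    return sim, sample, alns, offsets


def test_metagene_uniform_coverage_is_flat_at_codon_resolution(uniform_metagene):
    """Uniform sampling (no initiation peak) gives a flat start-aligned
    profile; the simulator places P-sites on codon starts, so flatness is
    assessed on codon-binned density."""
    sim, sample, alns, offsets = uniform_metagene
    prof = metagene(alns, offsets, sim.model, sample, window=(0, 89))
    binned = prof.density_start.reshape(-1, 3).sum(axis=1)
    cv = binned.std() / binned.mean()
    assert cv < 0.1


def test_metagene_initiation_peak_localizes_to_offset_zero(small_sim):
    """A 5x dwell with the start codon in the P-site puts the profile
    maximum exactly at start-relative offset 0."""
    sample = "control_rep1"
    alns = small_sim.footprint_alignments(sample)
    offsets = OffsetTable(dict(small_sim.config.p_offsets))
    prof = metagene(alns, offsets, small_sim.model, sample, window=(24, 90))
    peak = prof.offsets_start[int(np.argmax(prof.density_start))]
    assert peak == 0


def test_metagene_single_read_is_indicator(toy_model):
    offsets = OffsetTable({28: 12})
    tr = toy_model.transcripts["a1"]
    aln = FootprintAlignment("r", "a1", tr.cds_start - 12 + 6, 28, "s")
    prof = metagene([aln], offsets, toy_model, "s", window=(12, 12))
    assert prof.density_start.sum() == pytest.approx(1.0)
    assert prof.density_start[12 + 6] == pytest.approx(1.0)


@pytest.mark.parametrize(
    "seq, clip, ref, expected",
    [
        # 6 soft-clipped As, reference continues with non-A: untemplated
        ("CGTACGTACGTACGTACGTACGAAAAAA", 6, "CGTACGTACGTACGTACGTACG" + "CGTTT", (6, True)),
        # terminal As matching a genomic A-run: templated
        ("CGTACGTACGTACGTACGTACGAAAAAA", 0, "CGTACGTACGTACGTACGTACGAAAAAA" + "TT", (6, False)),
        # run must be terminal
        ("CGTACGTACGTACGTACGTACGAAAAAG", 0, "CGTACGTACGTACGTACGTACGAAAAAG", (0, False)),
    ],
)
def test_polya_suffix_scan_plus_strand(seq, clip, ref, expected):
    aligned = len(seq) - clip
    aln = FootprintAlignment(
        read_id="r", ref="chr", five_prime_pos=0, length=len(seq), sample_id="s",
        strand="+", ref_start=0, ref_end=aligned,
        soft_clip_3p=seq[aligned:], seq=seq,
    )
    assert polyA_suffix_scan(aln, ref) == expected


def test_polya_suffix_scan_minus_strand_checks_T_run():
    # original read ends in 7 As, aligned on the minus strand with the
    # tail soft-clipped on the genomic left; templated iff genome has Ts
    seq = "CGTACGTACGTACGTACGTAC" + "A" * 7
    body_rc = "GTACGTACGTACGTACGTACG"  # revcomp of the body
    genome_t = "TTTTTTT" + body_rc + "ACGT"
    genome_c = "TTTCTTT" + body_rc + "ACGT"
    aln = FootprintAlignment(
        read_id="r", ref="chr", five_prime_pos=27, length=28, sample_id="s",
        strand="-", ref_start=7, ref_end=7 + 21,
        soft_clip_3p="A" * 7, seq=seq,
    )
    assert polyA_suffix_scan(aln, genome_t) == (7, False)
    assert polyA_suffix_scan(aln, genome_c) == (7, True)
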