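"""Shared fixtures: a hand-built toy transcriptome and small simulated
experiments reused across test modules."""

import numpy as np
import pytest

from ribopause.annotation import TranscriptomeModel, TranscriptRecord
from ribopause.simulate import PauseSpec, PolyASpec, SimulationConfig, Simulator


def make_toy_model() -> TranscriptomeModel:
    """Two genes on one chromosome.

    geneA (+): two isoforms sharing a single exon and CDS frame; isoform
    a2 has a 30 nt longer 3'UTR (exon extended), giving it a unique
    exonic region.  geneB (-): one two-exon isoform.

    Sequences are synthetic and deterministic.
    """
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))

    def seq(n):
        return "".join(bases[rng.integers(0, 4, n)])

    # geneA: exon [1000, 1150) on +; CDS transcript [30, 120) => 30 codons
    a1 = TranscriptRecord(
        "a1", "geneA", "chr1", "+", [(1000, 1150)], cds_start=30, cds_end=120
    )
    a2 = TranscriptRecord(
        "a2", "geneA", "chr1", "+", [(1000, 1180)], cds_start=30, cds_end=120
    )
    # geneB: exons [2000,2100) and [2200,2300) on -, 5'->3' order descending
    b1 = TranscriptRecord(
        "b1", "geneB", "chr1", "-", [(2200, 2300), (2000, 2100)],
        cds_start=60, cds_end=150,
    )
    shared = seq(150)
    seqs = {"a1": shared, "a2": shared + seq(30), "b1": seq(200)}
    return TranscriptomeModel(
        genes={"geneA": ["a1", "a2"], "geneB": ["b1"]},
        transcripts={"a1": a1, "a2": a2, "b1": b1},
        sequences=seqs,
        gene_names={"geneA": "geneA", "geneB": "geneB"},
    )


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def small_sim():
    """15 genes, poly(A) tails + decoys, one mutant-specific and one
    shared pause; used wherever a realistic but quick experiment helps."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=15,
        polya=PolyASpec(rate=0.002, templated_decoy_rate=0.001),
        decoy_a_runs=(8, 12, 20),
        pauses=(
            PauseSpec(gene="g0001", codon=60, genotypes=("mutant",)),
            PauseSpec(gene="g0002", codon=80, genotypes=None),
        ),
    )
    return Simulator(cfg)


@pytest.fixture(scope="session")
def small_design(small_sim):
    cfg = small_sim.config
    return {
        g: [f"{g}_rep{r}" for r in range(1, cfg.n_replicates + 1)]
        for g in cfg.genotypes
    }
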