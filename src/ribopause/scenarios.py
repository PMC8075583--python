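"""Standard simulated study designs used by the examples, the test
suite and the reproduction script.

Each builder returns a configured :class:`~ribopause.simulate.Simulator`
(or count matrix) realizing one verification scenario: pause recovery
with replicate/genotype structure, poly(A)-tail detection against
templated decoys, codon-occupancy null and dwell designs, and the TE /
buffering count experiments.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .simulate import (
    PauseSpec,
    PolyASpec,
    SimulationConfig,
    Simulator,
    simulate_te_experiment,
)

PAUSE_AMPLIFICATION = 30.0


def pause_design(
    seed: int,
    n_mutant_only: int = 10,
    n_shared: int = 5,
    n_partial: int = 5,
    amplification: float = PAUSE_AMPLIFICATION,
) -> Simulator:
    """A 50-gene, 3-replicate x 2-genotype experiment with pauses
    injected at well-expressed genes: ``n_mutant_only`` loci amplified in
    every mutant replicate, ``n_shared`` in every replicate of both
    genotypes, and ``n_partial`` in only two of the three mutant
    replicates (so the all-replicates rule must reject them).

    Pause codons sit away from the start/stop masked neighbourhoods.
    Truth lives in ``sim.manifest.pause_loci``.
    """
    base = SimulationConfig(seed=seed)
    structural = Simulator(base)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1717]))
    by_abundance = sorted(
        structural.manifest.gene_abundance,
        key=lambda g: -structural.manifest.gene_abundance[g],
    )
    n_total = n_mutant_only + n_shared + n_partial
    chosen = by_abundance[:n_total]
    specs = []
    for i, gene in enumerate(chosen):
        tr = structural.model.transcripts[structural.model.genes[gene][0]]
        codon = int(rng.integers(tr.cds_first_codon + 8, tr.cds_last_codon - 4))
        if i < n_mutant_only:
            genotypes, reps = ("mutant",), None
        elif i < n_mutant_only + n_shared:
            genotypes, reps = None, None  # both genotypes, every replicate
        else:
            genotypes, reps = ("mutant",), (1, 2)
        specs.append(
            PauseSpec(
                gene=gene,
                codon=codon,
                amplification=amplification,
                genotypes=genotypes,
                replicates=reps,
            )
        )
    return Simulator(replace(base, pauses=tuple(specs)))


def pause_truth_classes(sim: Simulator) -> dict[str, set[tuple[str, str, int, str]]]:
    """Expected locus keys per class from the manifest: loci amplified in
    all replicates of both genotypes are 'shared', of the mutant only are
    'mutant_only'; partial-replicate loci should not be reported."""
    cfg = sim.config
    all_reps = list(range(1, cfg.n_replicates + 1))
    out = {"shared": set(), "mutant_only": set(), "control_only": set(), "partial": set()}
    for locus in sim.manifest.pause_loci:
        key = (locus["gene"], locus["chrom"], locus["pos"], locus["strand"])
        if locus["replicates"] != all_reps:
            out["partial"].add(key)
        elif set(locus["genotypes"]) == set(cfg.genotypes):
            out["shared"].add(key)
        elif locus["genotypes"] == [cfg.genotypes[1]]:
            out["mutant_only"].add(key)
        else:
            out["control_only"].add(key)
    return out


def polya_design(
    seed: int,
    rate: float = 0.002,
    decoy_rate: float = 0.001,
    n_genes: int = 50,
) -> Simulator:
    """Footprints with untemplated poly(A) tails (6-15 nt, rate per read)
    plus genomic A-run decoys of 6-20 nt that template reads ending in
    adenosines; 20% of tail reads are emitted unmapped."""
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        polya=PolyASpec(rate=rate, templated_decoy_rate=decoy_rate),
        decoy_a_runs=(6, 8, 10, 12, 15, 18, 20),
    )
    return Simulator(cfg)


def codon_design(
    seed: int,
    dwell: dict[str, float] | None = None,
    n_genes: int = 200,
) -> Simulator:
    """Single-sample, single-isoform design for codon occupancy: uniform
    expression over ``n_genes`` transcripts, optional codon dwell
    multipliers (e.g. ``{"AGA": 3.0}``), no pauses, no initiation peak
    (so the null really is uniform over CDS codons)."""
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        isoform_probs=(1.0, 0.0, 0.0),
        expr_log2_sd=0.0,
        genotypes=("control",),
        n_replicates=1,
        init_amplification=1.0,
        dwell=tuple((dwell or {}).items()),
    )
    return Simulator(cfg)


def te_design(seed: int, delta_log2_te: float = 0.5, set_size: int = 100):
    """2000 background + ``set_size`` genes with a TE shift; NB counts at
    50 mean reads/gene, 3 replicates per genotype and assay."""
    return simulate_te_experiment(
        seed, n_background=2000, set_size=set_size, delta_log2_te=delta_log2_te
    )


def buffering_design(
    seed: int,
    n_genes: int = 2000,
    n_changed: int = 600,
    mrna_sd: float = 0.7,
    slope: float = 0.8,
    noise_sd: float = 0.25,
):
    """Translational buffering: a subset of genes gets transcriptional
    changes and TE moves against them (te = -slope * mrna + noise).
    Returns (CountMatrix, truth)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4242]))
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    changed = list(rng.choice(genes, size=n_changed, replace=False))
    mrna = {g: float(rng.normal(0.0, mrna_sd)) for g in changed}
    te = {g: float(-slope * mrna[g] + rng.normal(0.0, noise_sd)) for g in changed}
    return simulate_te_experiment(
        seed,
        n_background=n_genes,
        set_size=0,
        delta_log2_te=0.0,
        mrna_log2fc=mrna,
        te_log2fc=te,
    )
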