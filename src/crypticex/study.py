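"""Standard study fixtures: cohort designs, mixtures, and the end-to-end
amplicon experiment.

These encode the study conditions the pipeline is exercised under: a
whole-genome cohort of 7 affected foals, 4 obligate-carrier parents and 32
control horses; an RNA cohort of 5 affected and 6 controls; an amplicon
cohort of 2 affected and 4 controls whose RT-PCR mixtures contain two shared
canonical 306 bp haplotypes plus, in affected foals only, the 398 bp
cryptic-exon and 541 bp cryptic+extended-acceptor isoforms; and a
1,060-horse genotyping panel at the published carrier frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import amplicon as amp
from . import synthetic as syn
from .genemodel import GeneModel
from .segregation import CohortDesign


def wgs_cohort_design() -> CohortDesign:
    roles = {f"case{i:02d}": "case" for i in range(1, 8)}
    roles |= {f"carrier{i:02d}": "obligate_carrier" for i in range(1, 5)}
    roles |= {f"control{i:02d}": "control" for i in range(1, 33)}
    return CohortDesign(roles)


def rna_cohort_design() -> CohortDesign:
    roles = {f"case{i:02d}": "case" for i in range(1, 6)}
    roles |= {f"control{i:02d}": "control" for i in range(1, 7)}
    return CohortDesign(roles)


def amplicon_cohort_design() -> CohortDesign:
    roles = {"case01": "case", "case02": "case"}
    roles |= {f"control{i:02d}": "control" for i in range(1, 5)}
    return CohortDesign(roles)


def rna_isoform_weights(design: CohortDesign, cryptic: bool = True):
    """Spliced-read isoform weights: affected foals express the cryptic
    isoforms alongside residual canonical transcript; controls do not."""
    weights = {}
    for s in design.cases:
        if cryptic:
            weights[s] = {"canonical": 0.5, "cryptic": 0.35, "cryptic_extended": 0.15}
        else:
            weights[s] = {"canonical": 1.0}
    for s in design.controls:
        weights[s] = {"canonical": 1.0}
    return weights


def amplicon_mixtures(design: CohortDesign, cryptic: bool = True):
    """RT-PCR product mixtures: three comparable bands in affected foals,
    two canonical haplotypes in every sample."""
    mixtures = {}
    for s in design.cases:
        if cryptic:
            mixtures[s] = {
                "canonical_A": 0.2, "canonical_B": 0.2,
                "cryptic": 0.3, "cryptic_extended": 0.3,
            }
        else:
            mixtures[s] = {"canonical_A": 0.5, "canonical_B": 0.5}
    for s in design.controls:
        mixtures[s] = {"canonical_A": 0.5, "canonical_B": 0.5}
    return mixtures


def default_primers() -> amp.PrimerPair:
    return amp.PrimerPair(syn.DEFAULT_FORWARD_PRIMER, syn.DEFAULT_REVERSE_PRIMER)


@dataclass
class AmpliconRunResult:
    clusters: list
    significant: list
    classes: dict[int, str]
    consensi: dict[int, amp.ConsensusSequence]
    structures: dict[int, amp.IsoformStructure]
    totals: dict[str, int]
    n_shared: int
    n_case_only: int


def run_amplicon_experiment(
    contig: str,
    gene: GeneModel,
    truth: syn.PlantedTruth,
    seed: int,
    n_reads: int = 1000,
    error_rate: float = 0.01,
    subsample_n: int = 100_000,
    identity: float = 0.98,
    sig_fraction: float = 0.10,
    consensus_k: int = 25,
    min_reads_classify: int = 5,
    corrupted_primer_fraction: float = 0.0,
    cryptic: bool = True,
    map_consensi: bool = True,
) -> AmpliconRunResult:
    """Simulate the amplicon cohort and run the full long-read chain."""
    design = amplicon_cohort_design()
    primers = default_primers()
    inserts = syn.amplicon_inserts(contig, gene, truth, primers)
    reads = syn.simulate_amplicon_reads(
        inserts,
        amplicon_mixtures(design, cryptic=cryptic),
        primers,
        error_rate=error_rate,
        n_reads=n_reads,
        seed=seed,
        corrupted_primer_fraction=corrupted_primer_fraction,
    )
    reads = amp.quality_filter(reads)
    reads = amp.subsample_reads(reads, subsample_n, seed=seed + 1)
    trimmed, _rejected = amp.trim_all(reads, primers)
    totals: dict[str, int] = {}
    for r in trimmed:
        totals[r.sample] = totals.get(r.sample, 0) + 1
    clusters = amp.greedy_cluster(trimmed, threshold=identity)
    significant = amp.significant_clusters(clusters, totals, fraction=sig_fraction)
    classes = amp.classify_clusters(significant, design, min_reads=min_reads_classify)
    reads_by_id = {r.id: r for r in trimmed}
    consensi, structures = {}, {}
    if map_consensi:
        for c in significant:
            cons = amp.consensus(c, reads_by_id, k=consensus_k, seed=seed + 2 + c.id)
            consensi[c.id] = cons
            structures[c.id] = amp.map_consensus(cons.sequence, contig, gene)
    return AmpliconRunResult(
        clusters=clusters,
        significant=significant,
        classes=classes,
        consensi=consensi,
        structures=structures,
        totals=totals,
        n_shared=sum(1 for v in classes.values() if v == "shared"),
        n_case_only=sum(1 for v in classes.values() if v == "case_only"),
    )


def cohort_variants(truth: syn.PlantedTruth, gene: GeneModel, n_decoys: int = 60, seed: int = 0):
    """Causal variant plus background decoys for the cohort VCF."""
    causal = syn.SimVariant(
        pos=truth.variant_position,
        ref=truth.variant_ref,
        alt=truth.variant_alt,
        gene=gene.gene_name,
        effect="intron_variant",
        impact="MODIFIER",
        causal=True,
    )
    lo = max(1, truth.variant_position - 3000)
    hi = truth.variant_position + 3000
    decoys = syn.make_decoy_variants(
        (lo - 1, hi), n_decoys, seed=seed, forbidden={truth.variant_position}
    )
    variants = sorted([causal] + decoys, key=lambda v: v.pos)
    return variants
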