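"""End-to-end orchestration: simulate -> segregate -> cryptic -> amplicon ->
translate -> allele frequency, with a JSON report and per-stage manifests.

Reruns with an identical config produce byte-identical outputs; every stage
records its parameters and products in the manifest so each report field
traces to the stage that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import amplicon as amp
from . import cryptic as cx
from . import io as cio
from . import orf, popgen, segregation as seg, study, synthetic as syn

log = logging.getLogger("crypticex")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str = "crypticex_run"
    seed: int = 0
    strand: str = "+"
    cryptic_enabled: bool = True
    # segregation
    p_threshold: float = 1e-11
    q_background: float = 0.0
    n_decoys: int = 60
    home_breed: str = "Quarter Horse"
    # RNA evidence
    rna_depth: int = 200
    min_case_reads: int = 10
    max_control_fraction: float = 0.05
    # amplicons
    amplicon_reads: int = 1000
    amplicon_error: float = 0.01
    subsample_n: int = 100_000
    identity: float = 0.98
    sig_frac: float = 0.10
    consensus_k: int = 25
    min_reads_classify: int = 5
    # panel
    panel_n: int = 1060
    panel_q: float = 0.0118

    def validate(self):
        for name in ("identity", "sig_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.p_threshold <= 0:
            raise ValueError("p_threshold must be positive")


def _sub_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(x % 2**31) for x in state]


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the report dict (also written to disk)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _sub_seeds(config.seed, 8)
    manifest: list[dict] = []
    report: dict = {"config": dataclasses.asdict(config)}

    def stage(name, params):
        log.info("stage %s: %s", name, params)
        manifest.append({"stage": name, "params": params, "products": []})

    def product(path):
        manifest[-1]["products"].append(Path(path).name)

    # ---- simulate ---------------------------------------------------------
    try:
        stage("simulate", {"seed": seeds[0], "strand": config.strand,
                           "cryptic": config.cryptic_enabled})
        spec = syn.LocusSpec(strand=config.strand, seed=seeds[0])
        if not config.cryptic_enabled:
            spec.cryptic_exon = None
            spec.extended_acceptor_shift = 0
        contig, gene, truth = syn.build_toy_locus(spec)
        cio.write_fasta(out / "reference.fa", {spec.contig_name: contig})
        from .genemodel import write_gff3

        write_gff3(out / "gene.gff3", gene)
        wgs = study.wgs_cohort_design()
        cio.write_design_tsv(out / "wgs_design.tsv", wgs.roles)
        variants = study.cohort_variants(truth, gene, config.n_decoys, seed=seeds[1]) \
            if config.cryptic_enabled else study.cohort_variants(
                dataclasses.replace(truth, variant_position=gene.exons[1][1] + 100,
                                    variant_ref="G", variant_alt="C"),
                gene, config.n_decoys, seed=seeds[1])
        gts = syn.simulate_cohort_genotypes(wgs, variants, config.q_background, seed=seeds[2])
        cio.write_cohort_vcf(out / "cohort.vcf", spec.contig_name, spec.contig_length,
                             variants, gts, list(wgs.roles))
        rna = study.rna_cohort_design()
        cio.write_design_tsv(out / "rna_design.tsv", rna.roles)
        sreads = syn.simulate_spliced_reads(
            gene, truth.isoform_structures,
            study.rna_isoform_weights(rna, cryptic=config.cryptic_enabled),
            depth=config.rna_depth, seed=seeds[3])
        cio.write_bed12(out / "spliced_reads.bed", sreads)
        panel = syn.simulate_panel(config.panel_n, config.panel_q, seed=seeds[4])
        truth.panel_counts = (panel.n_het, panel.n_homalt, panel.n_total)
        cio.write_panel_tsv(out / "panel.tsv", panel)
        cio.write_json(out / "truth.json", truth.to_jsonable())
        for p in ("reference.fa", "gene.gff3", "cohort.vcf", "spliced_reads.bed",
                  "panel.tsv", "truth.json"):
            product(out / p)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    # ---- segregate --------------------------------------------------------
    try:
        stage("segregate", {"p_threshold": config.p_threshold})
        records = seg.parse_vcf(out / "cohort.vcf")
        kept, assoc = seg.candidate_filter_chain(
            records, wgs, p_threshold=config.p_threshold)
        region = seg.define_candidate_region(kept) if kept else None
        hgvs = None
        causal_rec = next(
            (v for v in kept if config.cryptic_enabled
             and v.pos == truth.variant_position), None)
        if causal_rec is not None and not gene.is_exonic(causal_rec.pos - 1):
            hgvs = seg.hgvs_intronic_name(causal_rec, gene).rendered
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\tgene\teffect\timpact\tp_allelic\n")
            for v in kept:
                a = v.annotations[0] if v.annotations else None
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                    f"{a.gene if a else '.'}\t{a.effect if a else '.'}\t"
                    f"{a.impact if a else '.'}\t{assoc[v.key].p_allelic:.3e}\n")
        product(out / "candidates.tsv")
        report["segregation"] = {
            "n_candidates": len(kept),
            "candidate_region": dataclasses.asdict(region) if region else None,
            "hgvs": hgvs,
            "causal_recovered": causal_rec is not None,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("segregate", e) from e

    # ---- cryptic exon -----------------------------------------------------
    try:
        stage("cryptic", {"min_case_reads": config.min_case_reads,
                          "max_control_fraction": config.max_control_fraction})
        sreads2 = cio.read_bed12(out / "spliced_reads.bed")
        profiles = cx.intron_coverage(sreads2, gene)
        calls = cx.call_cryptic_exons(
            profiles, rna, gene,
            min_case_reads=config.min_case_reads,
            max_control_fraction=config.max_control_fraction)
        offset = None
        if calls and causal_rec is not None:
            offset = cx.locate_variant_in_exon(calls[0], causal_rec)
        report["cryptic"] = {
            "n_calls": len(calls),
            "calls": [
                {"intron_index": c.intron_index, "interval": list(c.interval),
                 "case_support": c.case_read_support,
                 "control_support": c.control_read_support,
                 "junction_supported": c.junction_supported}
                for c in calls
            ],
            "variant_offset_in_exon": offset,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("cryptic", e) from e

    # ---- amplicons --------------------------------------------------------
    try:
        stage("amplicon", {"n_reads": config.amplicon_reads,
                           "identity": config.identity, "sig_frac": config.sig_frac})
        res = study.run_amplicon_experiment(
            contig, gene, truth, seed=seeds[5],
            n_reads=config.amplicon_reads, error_rate=config.amplicon_error,
            subsample_n=config.subsample_n, identity=config.identity,
            sig_fraction=config.sig_frac, consensus_k=config.consensus_k,
            min_reads_classify=config.min_reads_classify,
            cryptic=config.cryptic_enabled)
        cio.write_fasta(
            out / "consensus.fa",
            {f"cluster{cid}": cons.sequence for cid, cons in sorted(res.consensi.items())})
        product(out / "consensus.fa")
        report["amplicon"] = {
            "n_clusters": len(res.clusters),
            "n_significant": len(res.significant),
            "n_shared": res.n_shared,
            "n_case_only": res.n_case_only,
            "inventory": [
                {"cluster": c.id, "class": res.classes[c.id],
                 "mean_length": round(c.mean_length, 1),
                 "consensus_length": len(res.consensi[c.id].sequence)
                 if c.id in res.consensi else None,
                 "novel_blocks": [list(b) for b in res.structures[c.id].novel_blocks]
                 if c.id in res.structures else [],
                 "extended_boundaries": res.structures[c.id].extended_boundaries
                 if c.id in res.structures else []}
                for c in res.significant
            ],
        }
        amp_result = res
    except Exception as e:  # noqa: BLE001
        raise StageError("amplicon", e) from e

    # ---- translate --------------------------------------------------------
    try:
        stage("translate", {})
        translation = None
        novel_blocks = sorted(
            {tuple(b) for cid, s in amp_result.structures.items()
             if amp_result.classes.get(cid) == "case_only" for b in s.novel_blocks})
        if novel_blocks:
            novel_full = sorted(list(gene.exons) + [novel_blocks[0]])
            aa = orf.ptc_after_insertion(list(gene.exons), novel_full, contig, gene)
            pred = orf.predict_coding(contig, gene, novel_full)
            translation = {
                "aa_after_insertion": aa,
                "stop_codon": pred.stop_codon,
                "ptc": pred.ptc,
                "nmd_candidate": pred.nmd_candidate,
            }
        report["translation"] = translation
    except Exception as e:  # noqa: BLE001
        raise StageError("translate", e) from e

    # ---- allele frequency -------------------------------------------------
    try:
        stage("allelefreq", {"n": config.panel_n, "q": config.panel_q})
        counts = cio.read_panel_tsv(out / "panel.tsv")
        est = popgen.allele_frequency(counts)
        report["allele_frequency"] = {
            "f": est.f, "se": est.se,
            "counts": dataclasses.asdict(counts),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("allelefreq", e) from e

    report["manifest"] = manifest
    cio.write_json(out / "report.json", report)
    with open(out / "report.txt", "w") as fh:
        fh.write(render_report(report))
    return report


def render_report(report: dict) -> str:
    lines = ["crypticex pipeline report", "=" * 26, ""]
    s = report.get("segregation", {})
    lines.append(f"candidate variants after filtering: {s.get('n_candidates')}")
    if s.get("candidate_region"):
        r = s["candidate_region"]
        lines.append(
            f"candidate region: {r['chrom']}:{r['start']}-{r['end']} (span {r['span']} bp)")
    if s.get("hgvs"):
        lines.append(f"causal variant HGVS: {s['hgvs']}")
    c = report.get("cryptic", {})
    lines.append(f"cryptic-exon calls: {c.get('n_calls')}")
    if c.get("variant_offset_in_exon"):
        lines.append(f"variant offset inside cryptic exon: {c['variant_offset_in_exon']}")
    a = report.get("amplicon", {})
    lines.append(
        f"amplicon clusters: {a.get('n_clusters')} total, {a.get('n_significant')} "
        f"significant ({a.get('n_shared')} shared, {a.get('n_case_only')} case-only)")
    t = report.get("translation")
    if t:
        lines.append(
            f"translation: stop {t['stop_codon']} after {t['aa_after_insertion']} aa "
            f"(PTC={t['ptc']}, NMD candidate={t['nmd_candidate']})")
    f = report.get("allele_frequency", {})
    if f:
        lines.append(f"allele frequency: {f['f']:.4f} (SE {f['se']:.4f})")
    return "\n".join(lines) + "\n"
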