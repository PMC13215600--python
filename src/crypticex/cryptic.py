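"""Cryptic (pseudo-)exon calling from spliced-read block evidence.

Spliced alignments are consumed as BED12-style block records, so the stage
is testable without an aligner; an adapter from spliced BAM/CRAM alignments
is a documented extension point.  For every intron of the gene model, read
blocks lying strictly inside the intron are merged into maximal covered
intervals; an interval is called a cryptic exon when case support clears a
read-count threshold and control leakage stays below a fraction of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genemodel import GeneModel, Interval
from .segregation import CohortDesign, VariantRecord


@dataclass
class SplicedReadBlocks:
    """One spliced read: ordered, non-overlapping genomic block intervals."""

    sample: str
    blocks: list[Interval]
    isoform_tag: str | None = None
    chrom: str = "."
    strand: str = "+"

    def __post_init__(self):
        self.blocks = sorted(tuple(b) for b in self.blocks)
        for (s, e) in self.blocks:
            if e <= s:
                raise ValueError("empty block")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b[0] < a[1]:
                raise ValueError("overlapping blocks in one read")


@dataclass
class IntronProfile:
    """A merged covered interval inside one intron."""

    intron_index: int  # 1-based, transcription order
    interval: Interval
    support: dict[str, int] = field(default_factory=dict)  # sample -> reads
    junction_reads: int = 0  # reads that also carry a flanking-exon block


@dataclass
class CrypticExonCall:
    gene: str
    intron_index: int
    interval: Interval
    case_read_support: int
    control_read_support: int
    junction_supported: bool
    strand: str = "+"
    chrom: str = "."


def _merge(intervals: list[Interval]) -> list[Interval]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def intron_coverage(reads, gene: GeneModel) -> list[IntronProfile]:
    """Merged intronic coverage intervals with per-sample read counts.

    Only blocks lying strictly inside an intron contribute.  Read input
    order does not affect the result.
    """
    if len(gene.exons) < 2:
        raise ValueError("gene model needs >= 2 exons to have introns")
    introns = gene.introns_tx_order()
    profiles: list[IntronProfile] = []
    for idx, (istart, iend) in enumerate(introns, start=1):
        inner = []  # (read, block) pairs with the block inside this intron
        for r in reads:
            for b in r.blocks:
                if istart <= b[0] and b[1] <= iend:
                    inner.append((r, b))
        if not inner:
            continue
        for iv in _merge([b for _, b in inner]):
            prof = IntronProfile(intron_index=idx, interval=iv)
            for r, b in inner:
                if iv[0] <= b[0] and b[1] <= iv[1]:
                    prof.support[r.sample] = prof.support.get(r.sample, 0) + 1
                    if any(
                        bb[0] < istart or bb[1] > iend  # a block outside the intron
                        for bb in r.blocks
                        if bb != b
                    ):
                        prof.junction_reads += 1
            profiles.append(prof)
    return profiles


def call_cryptic_exons(
    profiles,
    design: CohortDesign,
    gene: GeneModel,
    min_case_reads: int = 10,
    max_control_fraction: float = 0.05,
) -> list[CrypticExonCall]:
    """Emit calls where case support is high and control leakage low."""
    cases = set(design.cases)
    controls = set(design.controls)
    calls = []
    for p in profiles:
        case_n = sum(n for s, n in p.support.items() if s in cases)
        ctrl_n = sum(n for s, n in p.support.items() if s in controls)
        if case_n < min_case_reads:
            continue
        if case_n and ctrl_n / case_n > max_control_fraction:
            continue
        calls.append(
            CrypticExonCall(
                gene=gene.gene_name,
                intron_index=p.intron_index,
                interval=p.interval,
                case_read_support=case_n,
                control_read_support=ctrl_n,
                junction_supported=p.junction_reads > 0,
                strand=gene.strand,
                chrom=gene.chrom,
            )
        )
    return calls


def locate_variant_in_exon(call: CrypticExonCall, variant: VariantRecord) -> int | None:
    """1-based offset of the variant from the coding-strand 5' end of the call.

    Returns None when the variant lies outside the called interval.  On a
    minus-strand gene the 5' end is the genomic right edge, so "the eighth
    base pair of the cryptic exon" is well-defined on either strand.
    """
    g = variant.pos - 1
    s, e = call.interval
    if not s <= g < e:
        return None
    return (g - s + 1) if call.strand == "+" else (e - g)
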