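"""Transcript assembly, translation and premature-stop characterisation.

Builds mRNA sequences from exon structures, translates from the annotated
start with the standard genetic code, and measures how far translation
proceeds once a novel (cryptic) block is spliced in before hitting a
premature termination codon (PTC).  An advisory NMD flag uses the classic
55-nt last-exon-junction rule; it is never used as a filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .amplicon import IsoformStructure
from .genemodel import GeneModel, Interval, revcomp

_B = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_B)
    for j, b in enumerate(_B)
    for k, c in enumerate(_B)
}
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class CodingPrediction:
    peptide: str
    stop_codon: str | None
    stop_codon_index: int | None  # 1-based codon number of the stop
    ptc: bool
    aa_after_insertion: int | None = None
    nmd_candidate: bool = False
    frameshift: bool = False


def splice_mrna(reference: str, structure, strand: str) -> str:
    """Concatenate exonic sequence in transcription order (revcomp on '-')."""
    blocks = structure.all_blocks if isinstance(structure, IsoformStructure) else sorted(structure)
    for s, e in blocks:
        if s < 0 or e > len(reference) or e <= s:
            raise ValueError(f"block ({s}, {e}) out of reference bounds")
    seq = "".join(reference[s:e] for s, e in blocks)
    return seq if strand == "+" else revcomp(seq)


def translate_cds(
    mrna: str,
    cds_offset: int,
    junction_offsets: list[int] | None = None,
    canonical_stop_codon_index: int | None = None,
) -> CodingPrediction:
    """Translate from ``cds_offset`` (0-based) to the first stop codon.

    ``junction_offsets`` are exon-exon junction positions in mRNA
    coordinates; a stop more than 55 nt upstream of the last junction marks
    the transcript as an NMD candidate.  ``canonical_stop_codon_index``
    (1-based) makes the ``ptc`` flag precise; without it any stop before the
    end of the mRNA open reading frame is not by itself premature.
    """
    if cds_offset >= len(mrna) or cds_offset < 0:
        raise ValueError("cds_offset outside the mRNA")
    mrna = mrna.upper()
    peptide = []
    stop_codon = None
    stop_index = None
    for ci, off in enumerate(range(cds_offset, len(mrna) - 2, 3), start=1):
        codon = mrna[off : off + 3]
        if any(b not in "ACGT" for b in codon):
            raise ValueError(f"non-ACGT base in codon {codon!r} at offset {off}")
        aa = CODON_TABLE[codon]
        if aa == "*":
            stop_codon = codon
            stop_index = ci
            break
        peptide.append(aa)
    ptc = False
    if stop_codon is None:
        warnings.warn("no stop codon before the end of the mRNA")
    elif canonical_stop_codon_index is not None:
        ptc = stop_index < canonical_stop_codon_index
    nmd = False
    if stop_codon is not None and junction_offsets:
        stop_end = cds_offset + 3 * stop_index
        nmd = stop_end < max(junction_offsets) - 55
    return CodingPrediction(
        peptide="".join(peptide),
        stop_codon=stop_codon,
        stop_codon_index=stop_index,
        ptc=ptc,
        nmd_candidate=nmd,
    )


def _cds_offset_in(gene: GeneModel, blocks: list[Interval]) -> int:
    start_g = gene.cds_start if gene.strand == "+" else gene.cds_end - 1
    return gene.mrna_offset_of(start_g, blocks)


def _junctions(gene: GeneModel, blocks: list[Interval]) -> list[int]:
    tx_blocks = sorted(blocks, reverse=gene.strand == "-")
    offs, acc = [], 0
    for s, e in tx_blocks[:-1]:
        acc += e - s
        offs.append(acc)
    return offs


def predict_coding(reference: str, gene: GeneModel, structure) -> CodingPrediction:
    """Splice, translate, and flag PTC/NMD for one isoform structure."""
    blocks = structure.all_blocks if isinstance(structure, IsoformStructure) else sorted(structure)
    mrna = splice_mrna(reference, blocks, gene.strand)
    cds_off = _cds_offset_in(gene, blocks)
    canon_mrna = splice_mrna(reference, gene.exons, gene.strand)
    canon = translate_cds(canon_mrna, _cds_offset_in(gene, gene.exons))
    return translate_cds(
        mrna,
        cds_off,
        junction_offsets=_junctions(gene, blocks),
        canonical_stop_codon_index=canon.stop_codon_index,
    )


def ptc_after_insertion(canonical, novel, reference: str, gene: GeneModel) -> int | None:
    """Complete codons translated from the first codon overlapping the first
    novel block up to (excluding) the stop codon; None when no premature
    stop occurs before the canonical stop.

    A frame-shifting insertion (length not a multiple of 3) still counts to
    the encountered stop, with a warning.
    """
    canon_blocks = canonical.all_blocks if isinstance(canonical, IsoformStructure) else sorted(canonical)
    novel_blocks_all = novel.all_blocks if isinstance(novel, IsoformStructure) else sorted(novel)
    extra = [b for b in novel_blocks_all if b not in canon_blocks]
    if not extra:
        raise ValueError("novel structure has no block absent from the canonical one")
    ins_len = sum(e - s for s, e in extra)
    mrna = splice_mrna(reference, novel_blocks_all, gene.strand)
    cds_off = _cds_offset_in(gene, novel_blocks_all)
    pred = translate_cds(mrna, cds_off)
    if pred.stop_codon_index is None:
        return None
    extra_tx = sorted(extra, reverse=gene.strand == "-")
    first_novel = extra_tx[0]
    nb_start = first_novel[0] if gene.strand == "+" else first_novel[1] - 1
    nb_off = gene.mrna_offset_of(nb_start, novel_blocks_all)
    first_codon = (nb_off - cds_off) // 3  # 0-based codon overlapping the block
    stop_codon0 = pred.stop_codon_index - 1
    if ins_len % 3 != 0:
        # a frame shift only materialises when translation runs past the
        # insertion; an internal stop keeps the reading frame intact
        last_extra_end = max(
            gene.mrna_offset_of(b[1] - 1 if gene.strand == "+" else b[0], novel_blocks_all)
            for b in extra
        )
        if cds_off + 3 * stop_codon0 > last_extra_end:
            warnings.warn(
                f"insertion length {ins_len} is not a multiple of 3 (frameshift)"
            )
    # premature only if the stop is not the canonical one
    canon_mrna = splice_mrna(reference, canon_blocks, gene.strand)
    canon = translate_cds(canon_mrna, _cds_offset_in(gene, canon_blocks))
    if canon.stop_codon_index is not None and ins_len % 3 == 0:
        if stop_codon0 == canon.stop_codon_index - 1 + ins_len // 3:
            return None
    return stop_codon0 - first_codon
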