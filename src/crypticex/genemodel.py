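"""Single-transcript gene models and coordinate arithmetic.

All in-memory coordinates are 0-based half-open on the forward (plus) strand
of the contig; conversion to the 1-based inclusive conventions of GFF3/VCF
happens only at I/O boundaries.  One transcript is modelled at a time, which
is all the downstream cryptic-exon and ORF machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One annotated transcript: exon chain plus a CDS span.

    ``exons`` are stored sorted by genomic coordinate; ``cds_start`` and
    ``cds_end`` delimit the coding span on the genome (0-based half-open),
    so on the minus strand translation begins at ``cds_end``.
    """

    gene_name: str
    transcript_label: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"empty exon interval ({s}, {e})")
        for (a, b) in zip(self.exons, self.exons[1:]):
            if b[0] < a[1]:
                raise ValueError("exons overlap")
        if not any(s <= self.cds_start < e for s, e in self.exons):
            raise ValueError("cds_start does not fall inside an exon")

    # -- geometry ---------------------------------------------------------

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def introns(self) -> list[Interval]:
        """Introns in genomic order (0-based half-open)."""
        return [(a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])]

    def exons_tx_order(self) -> list[Interval]:
        """Exons in transcription order (5' -> 3' of the mRNA)."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns_tx_order(self) -> list[Interval]:
        return self.introns() if self.strand == "+" else list(reversed(self.introns()))

    def intron_index_of(self, gpos: int) -> int | None:
        """1-based intron number (transcription order) containing ``gpos``, or None."""
        for i, (s, e) in enumerate(self.introns_tx_order(), start=1):
            if s <= gpos < e:
                return i
        return None

    # -- coding coordinates ----------------------------------------------

    def coding_intervals_tx_order(self) -> list[Interval]:
        """Per-exon intersections with the CDS span, in transcription order."""
        out = []
        for s, e in self.exons_tx_order():
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return out

    def coding_length(self) -> int:
        return sum(e - s for s, e in self.coding_intervals_tx_order())

    def cdna_coding_position(self, gpos: int) -> int:
        """1-based cDNA coding coordinate (c.) of an exonic coding base."""
        c = 0
        for s, e in self.coding_intervals_tx_order():
            if s <= gpos < e:
                offset = (gpos - s) if self.strand == "+" else (e - 1 - gpos)
                return c + offset + 1
            c += e - s
        raise ValueError(f"position {gpos} is not an exonic coding base")

    def is_exonic(self, gpos: int) -> bool:
        return any(s <= gpos < e for s, e in self.exons)

    # -- sequence ---------------------------------------------------------

    def spliced_sequence(self, contig_seq: str, intervals: Sequence[Interval] | None = None) -> str:
        """mRNA sequence of the given blocks (default: annotated exons)."""
        blocks = sorted(intervals if intervals is not None else self.exons)
        seq = "".join(contig_seq[s:e] for s, e in blocks)
        return seq if self.strand == "+" else revcomp(seq)

    def mrna_offset_of(self, gpos: int, intervals: Sequence[Interval] | None = None) -> int:
        """0-based offset of genomic base ``gpos`` within the spliced mRNA."""
        blocks = sorted(intervals if intervals is not None else self.exons)
        if self.strand == "-":
            blocks = list(reversed(blocks))
        off = 0
        for s, e in blocks:
            if s <= gpos < e:
                return off + ((gpos - s) if self.strand == "+" else (e - 1 - gpos))
            off += e - s
        raise ValueError(f"position {gpos} not covered by the given blocks")


# ---------------------------------------------------------------------------
# GFF3 I/O


def write_gff3(path, gene: GeneModel) -> None:
    """Serialize a gene model as GFF3 (gene/mRNA/exon/CDS features, 1-based)."""
    gid, tid = gene.gene_name, gene.transcript_label
    s0, e0 = gene.span
    lines = ["##gff-version 3"]

    def row(ftype, s, e, attrs):
        return "\t".join(
            [gene.chrom, "crypticex", ftype, str(s + 1), str(e), ".", gene.strand, ".", attrs]
        )

    lines.append(row("gene", s0, e0, f"ID=gene:{gid};Name={gid}"))
    lines.append(row("mRNA", s0, e0, f"ID=transcript:{tid};Parent=gene:{gid};Name={tid}"))
    for i, (s, e) in enumerate(gene.exons, start=1):
        lines.append(row("exon", s, e, f"ID=exon:{tid}.{i};Parent=transcript:{tid}"))
        cs, ce = max(s, gene.cds_start), min(e, gene.cds_end)
        if cs < ce:
            lines.append(row("CDS", cs, ce, f"ID=cds:{tid};Parent=transcript:{tid}"))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> GeneModel:
    """Read a single-transcript gene model written by :func:`write_gff3`."""
    gene_name = transcript = chrom = strand = None
    exons: list[Interval] = []
    cds: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 row: {line!r}")
            ftype, s, e = f[2], int(f[3]) - 1, int(f[4])
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            if ftype == "gene":
                gene_name = attrs.get("Name", attrs.get("ID", "gene"))
                chrom, strand = f[0], f[6]
            elif ftype == "mRNA":
                transcript = attrs.get("Name", attrs.get("ID", "tx"))
            elif ftype == "exon":
                exons.append((s, e))
            elif ftype == "CDS":
                cds.append((s, e))
    if not exons or gene_name is None:
        raise ValueError("no gene/exon features found")
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    return GeneModel(gene_name, transcript or "tx", chrom, strand, exons, cds_start, cds_end)
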