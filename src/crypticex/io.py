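"""Readers and writers for the plain-text formats the pipeline exchanges.

VCF/GFF3 are 1-based inclusive, BED12 is 0-based half-open; everything in
memory stays 0-based half-open and is converted here.
"""

from __future__ import annotations

import csv
import json
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GT_CODE = {"homref": "0/0", "het": "0/1", "homalt": "1/1", "missing": "./."}


def write_fasta(path, records: Mapping[str, str]) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fastq(path, reads) -> None:
    """Write AmpliconRead-like objects (id, sequence, mean_quality) as FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            q = int(round(r.mean_quality)) if r.mean_quality is not None else 30
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{chr(33 + min(q, 60)) * len(r.sequence)}\n")


def read_fastq(path):
    """Yield (id, sequence, mean_phred) tuples."""
    for rec in SeqIO.parse(path, "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        yield rec.id, str(rec.seq), (sum(quals) / len(quals) if quals else None)


# ---------------------------------------------------------------------------
# BED12 spliced-read block records


def write_bed12(path, records) -> None:
    """Write SplicedReadBlocks records; read name is ``sample|index|isoform``."""
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            blocks = sorted(r.blocks)
            start, end = blocks[0][0], blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - start) for s, _ in blocks)
            name = f"{r.sample}|{i}|{r.isoform_tag or '.'}"
            fh.write(
                f"{r.chrom}\t{start}\t{end}\t{name}\t0\t{r.strand}\t{start}\t{end}\t0,0,0\t"
                f"{len(blocks)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path):
    """Parse BED12 rows back into SplicedReadBlocks records."""
    from .cryptic import SplicedReadBlocks  # local import avoids a cycle

    out = []
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"line {n}: BED12 requires 12 columns, got {len(f)}")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            nblocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != nblocks or len(offsets) != nblocks:
                raise ValueError(f"line {n}: blockCount disagrees with blockSizes/blockStarts")
            blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            parts = name.split("|")
            sample = parts[0]
            isoform = parts[2] if len(parts) > 2 and parts[2] != "." else None
            out.append(
                SplicedReadBlocks(sample=sample, blocks=blocks, isoform_tag=isoform,
                                  chrom=chrom, strand=strand)
            )
    return out


# ---------------------------------------------------------------------------
# VCF 4.2 cohort writer (parsing lives in segregation.parse_vcf)


def write_cohort_vcf(path, contig: str, contig_length: int, variants, genotypes, samples) -> None:
    """Write a multi-sample VCF 4.2 with SnpEff-style ANN annotations.

    ``variants`` supply pos (1-based), ref, alt, gene, effect, impact;
    ``genotypes`` is a parallel list of {sample: genotype-word} maps.
    """
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={contig_length}>",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "'Allele|Effect|Impact|Gene'\">",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for v, gts in zip(variants, genotypes):
            ann = f"ANN={v.alt}|{v.effect}|{v.impact}|{v.gene}"
            row = [contig, str(v.pos), ".", v.ref, v.alt, ".", "PASS", ann, "GT"]
            row += [GT_CODE[gts[s]] for s in samples]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# small TSV / JSON helpers


def write_design_tsv(path, roles: Mapping[str, str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample", "role"])
        for s, r in roles.items():
            w.writerow([s, r])


def read_design_tsv(path) -> dict[str, str]:
    with open(path) as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return {r["sample"]: r["role"] for r in rows}


def write_observations_tsv(path, obs: Mapping[tuple, set]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chrom", "pos", "alt", "breed"])
        for (chrom, pos, alt), breeds in obs.items():
            for b in sorted(breeds):
                w.writerow([chrom, pos, alt, b])


def read_observations_tsv(path) -> dict[tuple, set]:
    obs: dict[tuple, set] = {}
    with open(path) as fh:
        for r in csv.DictReader(fh, delimiter="\t"):
            obs.setdefault((r["chrom"], int(r["pos"]), r["alt"]), set()).add(r["breed"])
    return obs


def write_panel_tsv(path, counts) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["n_het", "n_homalt", "n_total"])
        w.writerow([counts.n_het, counts.n_homalt, counts.n_total])


def read_panel_tsv(path):
    from .popgen import GenotypeCounts

    with open(path) as fh:
        row = list(csv.DictReader(fh, delimiter="\t"))[0]
    return GenotypeCounts(int(row["n_het"]), int(row["n_homalt"]), int(row["n_total"]))


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
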